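"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementation: the
alignment oracle is a plain nested-loop Gotoh recurrence over Python
lists, and the translation oracle walks a hard-coded codon table.
"""

NEG = float("-inf")


def brute_semiglobal_score(query: str, ref: str, match=2.0, mismatch=-3.0,
                           gap_open=-10.0, gap_extend=-1.0) -> float:
    """Best affine-gap score of the full query against any ref substring."""
    q, r = query.upper(), ref.upper()
    m, n = len(q), len(r)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            if j > 0:
                s = match if q[i - 1] == r[j - 1] else mismatch
                M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                X[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_extend)
            Y[i][j] = max(M[i - 1][j] + gap_open, Y[i - 1][j] + gap_extend)
    return max(max(M[m]), max(Y[m]))


_CODONS = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_BASES):
    for _j, _b in enumerate(_BASES):
        for _k, _c in enumerate(_BASES):
            _CODONS[_a + _b + _c] = _AA[16 * _i + 4 * _j + _k]


def translate_to_stop(cdna: str, cds_offset: int = 1) -> str:
    """Residues from the start codon up to (excluding) the first stop."""
    out = []
    i = cds_offset - 1
    seq = cdna.upper()
    while i + 3 <= len(seq):
        aa = _CODONS[seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
        i += 3
    return "".join(out)


def apply_indel(cdna: str, kind: str, start: int, end: int, seq: str = "") -> str:
    """Re-apply an indel to the cDNA by direct string surgery (1-based)."""
    if kind == "deletion":
        return cdna[: start - 1] + cdna[end:]
    return cdna[:start] + seq + cdna[start:]
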