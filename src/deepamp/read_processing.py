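"""Demultiplexing, orientation, alignment and strand-stratified pileups.

Reads are compared against the *amplicon* subsequence of the reference
transcript (mirroring amplicon sequencing); barcode (MID) prefixes are
trimmed at demultiplexing, before orientation and alignment.

The aligner is an affine-gap semi-global (fit) alignment: the full read is
aligned against a substring of the reference, with free end gaps on the
reference side only. Traceback is deterministic with a fixed tie order
(diagonal > up > left, i.e. match state preferred over read-insertion over
reference-deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from Bio import SeqIO

NEG = -1e18

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Read:
    """A single amplicon read; ``strand`` is set by :func:`orient_read`.

    Reverse-strand reads are stored reverse-complemented (reference
    orientation) once oriented. ``strand`` is ``"+"``, ``"-"`` or ``None``
    (unoriented or unalignable).
    """

    id: str
    sequence: str
    qualities: str | None = None
    mid: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq), qualities=quals))
    return reads


def read_fasta(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class DemuxResult:
    by_sample: dict[str, list[Read]]
    unassigned: list[Read]

    @property
    def counts(self) -> dict[str, int]:
        c = {s: len(r) for s, r in self.by_sample.items()}
        c["unassigned"] = len(self.unassigned)
        return c


def demultiplex(reads: list[Read], mid_table: dict[str, str]) -> DemuxResult:
    """Partition reads by exact MID prefix match (tried on both strands).

    The matched MID is trimmed from the assigned read. Reads matching no
    MID go to the unassigned bin.
    """
    mids = list(mid_table.values())
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate MIDs in table")
    by_mid = {m.upper(): s for s, m in mid_table.items()}
    out: dict[str, list[Read]] = {s: [] for s in mid_table}
    unassigned: list[Read] = []
    for read in reads:
        assigned = False
        for seq in (read.sequence, revcomp(read.sequence)):
            for mid, sample in by_mid.items():
                if seq.upper().startswith(mid):
                    out[sample].append(
                        Read(read.id, seq[len(mid):],
                             qualities=None, mid=mid, strand=None)
                    )
                    assigned = True
                    break
            if assigned:
                break
        if not assigned:
            unassigned.append(read)
    return DemuxResult(out, unassigned)


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def orient_read(
    read: Read,
    reference: str,
    k: int = 11,
    min_hits: int = 4,
) -> Read:
    """Assign strand by shared k-mer support against the reference.

    Counts k-mers of the read (and of its reverse complement) that occur in
    the reference; the richer orientation wins, ties resolve to forward.
    Reads where neither orientation reaches ``min_hits`` shared k-mers are
    flagged unalignable (``strand=None``). A k-mer vote is robust to reads
    spanning large deletions/insertions, whose global alignment score
    against the contiguous reference is dominated by the event itself.
    """
    ref_kmers = _kmer_set(reference.upper(), k)
    fwd = sum(1 for km in _kmer_set(read.sequence.upper(), k) if km in ref_kmers)
    rc = revcomp(read.sequence)
    rev = sum(1 for km in _kmer_set(rc.upper(), k) if km in ref_kmers)
    if max(fwd, rev) < min_hits:
        return Read(read.id, read.sequence, read.qualities, read.mid, strand=None)
    if fwd >= rev:
        return Read(read.id, read.sequence, read.qualities, read.mid, strand="+")
    return Read(read.id, rc, None, read.mid, strand="-")


def orient_reads(
    reads: list[Read],
    reference: str,
    k: int = 11,
    min_hits: int = 4,
) -> tuple[list[Read], list[Read]]:
    """Orient a batch; returns (oriented, unalignable).

    Duplicate read sequences (ubiquitous in deep amplicon data) are
    resolved once and cached.
    """
    ref_kmers = _kmer_set(reference.upper(), k)
    cache: dict[str, tuple[str | None, str]] = {}
    oriented, bad = [], []
    for r in reads:
        seq = r.sequence.upper()
        if seq not in cache:
            fwd = sum(1 for km in _kmer_set(seq, k) if km in ref_kmers)
            rc = revcomp(seq)
            rev = sum(1 for km in _kmer_set(rc.upper(), k) if km in ref_kmers)
            if max(fwd, rev) < min_hits:
                cache[seq] = (None, seq)
            elif fwd >= rev:
                cache[seq] = ("+", seq)
            else:
                cache[seq] = ("-", rc)
        strand, oseq = cache[seq]
        o = Read(r.id, oseq if strand else r.sequence, None, r.mid, strand=strand)
        (oriented if o.strand else bad).append(o)
    return oriented, bad


def edit_distance(a: str, b: str, mode: str = "HW") -> int:
    """Thin wrapper over edlib (infix mode by default); used for screens."""
    return edlib.align(a, b, mode=mode)["editDistance"]


# ---------------------------------------------------------------------------
# affine-gap semi-global alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Alignment scores; a gap of length L costs open + (L-1) * extend.

    The default gap geometry (expensive open, mild extension) keeps 1-nt
    homopolymer indels from absorbing low-frequency substitutions while
    still letting a single long gap outscore a mangled gap-free alignment
    for splice-sized (100-250 nt) deletions flanked by ~150 nt of amplicon.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -10.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """Alignment of a full read against a reference substring.

    ``ref_start`` is the 1-based reference position of the first aligned
    reference base. ``ops`` is a run-length list over {'M', 'I', 'D'}
    (M = aligned column incl. mismatch, I = insertion in the read,
    D = deletion from the reference).
    """

    read_id: str
    ref_start: int
    ops: list[tuple[str, int]]
    score: float
    strand: str
    query: str

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.ops if op in "MI")
        if qlen != len(self.query):
            raise ValueError("ops do not cover the read")

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD") - 1

    @property
    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


def align_semiglobal(read: Read, reference: str, scoring: Scoring = Scoring()) -> Alignment:
    """Affine-gap fit alignment of ``read`` within ``reference``.

    Gotoh three-state dynamic programme, vectorised row-by-row: the
    reference-gap state within a row is resolved in closed form via a
    running prefix maximum. Ties in traceback prefer diagonal over up
    (read insertion) over left (reference deletion); the alignment end
    prefers the leftmost best-scoring reference column.
    """
    if not read.sequence:
        raise ValueError("empty read")
    q = read.sequence.upper()
    r = reference.upper()
    m, n = len(q), len(r)
    sc = scoring
    rarr = np.frombuffer(r.encode(), dtype=np.uint8)

    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in read (consumes reference, 'left')
    Y = np.full((m + 1, n + 1), NEG)  # gap in reference (consumes read, 'up')
    M[0, :] = 0.0  # free leading reference gap

    j_idx = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        sub = np.where(rarr == ord(q[i - 1]), sc.match, sc.mismatch)
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub + prev[:-1]
        Y[i, :] = np.maximum(M[i - 1, :] + sc.gap_open, Y[i - 1, :] + sc.gap_extend)
        # X[i,j] = max_{k<j} M[i,k] + open + (j-k-1)*extend
        t = M[i, :] - sc.gap_extend * j_idx
        c = np.maximum.accumulate(t)[:-1]
        X[i, 1:] = c + sc.gap_open + sc.gap_extend * (j_idx[1:] - 1)

    last = np.maximum(M[m, :], Y[m, :])
    j = int(np.argmax(last))  # leftmost best end column
    score = float(last[j])
    state = "M" if M[m, j] >= Y[m, j] else "Y"

    # traceback
    ops_rev: list[str] = []
    i = m
    while i > 0:
        if state == "M":
            ops_rev.append("M")
            pi, pj = i - 1, j - 1
            # predecessor preference: diagonal M > up Y > left X
            val = M[i, j] - (sc.match if q[i - 1] == r[j - 1] else sc.mismatch)
            if M[pi, pj] == val:
                state = "M"
            elif Y[pi, pj] == val:
                state = "Y"
            else:
                state = "X"
            i, j = pi, pj
        elif state == "Y":
            ops_rev.append("I")
            if M[i - 1, j] + sc.gap_open == Y[i, j]:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:  # X: deletion, consumes reference only
            ops_rev.append("D")
            if M[i, j - 1] + sc.gap_open == X[i, j]:
                state = "M"
            else:
                state = "X"
            j -= 1

    ref_start = j + 1
    ops: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return Alignment(read.id, ref_start, ops, score, read.strand or "+", read.sequence)


def align_reads(reads: list[Read], reference: str, scoring: Scoring = Scoring()) -> list[Alignment]:
    """Align a batch, caching the dynamic programme per unique (seq, strand)."""
    cache: dict[tuple[str, str | None], Alignment] = {}
    out = []
    for r in reads:
        key = (r.sequence.upper(), r.strand)
        hit = cache.get(key)
        if hit is None:
            hit = cache[key] = align_semiglobal(r, reference, scoring)
        out.append(Alignment(r.id, hit.ref_start, hit.ops, hit.score, hit.strand, hit.query))
    return out


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

_BASES = "ACGT-"
_BIDX = {b: i for i, b in enumerate(_BASES)}


class Pileup:
    """Per-position, strand-stratified base/deletion counts.

    ``counts[strand]`` is a 5 x L array over A/C/G/T/deletion for reference
    positions ``ref_offset .. ref_offset + L - 1`` (1-based, cDNA space).
    Insertions are kept separately, keyed by (anchor position, sequence).
    """

    def __init__(self, length: int, ref_offset: int = 1) -> None:
        self.ref_offset = ref_offset
        self.length = length
        self.counts = {
            "+": np.zeros((5, length), dtype=np.int64),
            "-": np.zeros((5, length), dtype=np.int64),
        }
        self.insertions: dict[tuple[int, str], dict[str, int]] = {}

    def _col(self, pos: int) -> int:
        if not self.ref_offset <= pos < self.ref_offset + self.length:
            raise IndexError(f"position {pos} outside pileup")
        return pos - self.ref_offset

    def add_base(self, pos: int, base: str, strand: str) -> None:
        b = base.upper()
        if b in _BIDX:
            self.counts[strand][_BIDX[b], self._col(pos)] += 1

    def add_insertion(self, anchor: int, seq: str, strand: str) -> None:
        key = (anchor, seq.upper())
        self.insertions.setdefault(key, {"+": 0, "-": 0})[strand] += 1

    def base_count(self, pos: int, base: str, strand: str) -> int:
        return int(self.counts[strand][_BIDX[base.upper()], self._col(pos)])

    def base_call_depth(self, pos: int, strand: str) -> int:
        """Reads with an actual base call (deletions excluded) at pos/strand."""
        return int(self.counts[strand][:4, self._col(pos)].sum())

    def coverage(self, pos: int) -> int:
        """All reads spanning pos (base calls + deletion observations), both strands."""
        c = self._col(pos)
        return int(self.counts["+"][:, c].sum() + self.counts["-"][:, c].sum())

    def positions(self):
        return range(self.ref_offset, self.ref_offset + self.length)

    def to_frame(self, reference: str | None = None):
        import pandas as pd

        rows = []
        for pos in self.positions():
            row = {"pos": pos}
            if reference is not None:
                row["ref"] = reference[pos - self.ref_offset]
            for strand in "+-":
                for b in _BASES:
                    row[f"{b}{strand}"] = self.base_count(pos, b, strand)
            rows.append(row)
        return pd.DataFrame(rows)


def build_pileup(
    alignments: list[Alignment],
    reference: str,
    ref_offset: int = 1,
) -> Pileup:
    """Accumulate strand-stratified counts from alignments on one reference."""
    pile = Pileup(len(reference), ref_offset=ref_offset)
    for aln in alignments:
        pos = aln.ref_start + ref_offset - 1  # cDNA coordinate
        qi = 0
        for op, length in aln.ops:
            if op == "M":
                for _ in range(length):
                    pile.add_base(pos, aln.query[qi], aln.strand)
                    pos += 1
                    qi += 1
            elif op == "D":
                for _ in range(length):
                    pile.add_base(pos, "-", aln.strand)
                    pos += 1
            else:  # I
                pile.add_insertion(pos - 1, aln.query[qi : qi + length], aln.strand)
                qi += length
    return pile


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------

def write_sam(
    alignments: list[Alignment],
    reference_name: str,
    reference_length: int,
    path: str | Path,
    ref_offset: int = 1,
) -> None:
    """Export alignments as SAM with the cDNA as the reference contig."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = aln.read_id
            a.query_sequence = aln.query
            a.flag = 16 if aln.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = aln.ref_start + ref_offset - 2  # SAM is 0-based
            a.mapping_quality = 60
            a.cigarstring = aln.cigar
            sam.write(a)
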