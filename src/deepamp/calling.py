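"""Low-frequency SNP calling and dual-detector INDEL discovery.

SNPs are accepted under a strand-bidirectional frequency rule: an
alternative base must reach the threshold (default 0.5%, inclusive) in the
forward *and* the reverse reads separately, over per-strand base-call
denominators. INDELs are discovered by two independent detectors — gap runs
in the semi-global alignments, and a seed-and-extend split-read scan — and
accepted only when both detectors report the same normalized event,
regardless of frequency (down to a single supporting read per detector).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .read_processing import Alignment, Pileup, Read
from .transcript import TranscriptModel

SNP_THRESHOLD = 0.005


@dataclass(frozen=True)
class SnpCall:
    cdna_position: int
    ref_base: str
    alt_base: str
    freq_forward: float
    freq_reverse: float
    freq_overall: float
    n_supporting: int

    @property
    def label(self) -> str:
        return f"c.{self.cdna_position}{self.ref_base}>{self.alt_base}"


@dataclass
class IndelCandidate:
    """Un-normalized indel event reported by one detector.

    Deletions carry a closed cDNA interval [start, end]; insertions sit
    between ``start`` and ``start + 1`` (start == end == anchor) and carry
    the inserted sequence.
    """

    kind: str  # deletion | insertion
    start: int
    end: int
    seq: str = ""
    read_ids: frozenset[str] = frozenset()
    detector: str = ""

    def __post_init__(self) -> None:
        if self.kind == "deletion" and self.end < self.start:
            raise ValueError("deletion interval empty")
        if self.kind == "insertion" and not self.seq:
            raise ValueError("insertion without sequence")

    @property
    def key(self) -> tuple:
        return (self.kind, self.start, self.end, self.seq)

    @property
    def length(self) -> int:
        return len(self.seq) if self.kind == "insertion" else self.end - self.start + 1

    @property
    def label(self) -> str:
        if self.kind == "deletion":
            if self.start == self.end:
                return f"c.{self.start}del"
            return f"c.{self.start}-{self.end}del"
        return f"c.{self.start + 1}ins{len(self.seq)}"


@dataclass
class IndelCall:
    """Cross-validated indel accepted by both detectors."""

    candidate: IndelCandidate
    read_ids: frozenset[str]
    frequency: float = float("nan")
    consensus_seq: str = ""
    validated_by: tuple[str, str] = ("gapped", "splitread")

    @property
    def kind(self) -> str:
        return self.candidate.kind

    @property
    def start(self) -> int:
        return self.candidate.start

    @property
    def end(self) -> int:
        return self.candidate.end

    @property
    def seq(self) -> str:
        return self.candidate.seq

    @property
    def label(self) -> str:
        return self.candidate.label


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def call_snps(
    pileup: Pileup,
    reference: str,
    threshold: float = SNP_THRESHOLD,
    log: list[str] | None = None,
) -> list[SnpCall]:
    """Strand-bidirectional SNP calls over base-call denominators.

    A call is emitted iff the per-strand alternative-base fraction is at
    least ``threshold`` on *both* strands ("at least" is inclusive: an alt
    at exactly the threshold on each strand is accepted). Positions with
    zero base-call depth on either strand are skipped and logged.
    """
    calls: list[SnpCall] = []
    for pos in pileup.positions():
        ref_base = reference[pos - pileup.ref_offset].upper()
        if ref_base not in "ACGT":
            continue
        df = pileup.base_call_depth(pos, "+")
        dr = pileup.base_call_depth(pos, "-")
        if df == 0 or dr == 0:
            if log is not None and pileup.coverage(pos) > 0:
                log.append(f"position {pos}: zero base-call depth on one strand, skipped")
            continue
        for alt in "ACGT":
            if alt == ref_base:
                continue
            nf = pileup.base_count(pos, alt, "+")
            nr = pileup.base_count(pos, alt, "-")
            if nf == 0 and nr == 0:
                continue
            ff, fr = nf / df, nr / dr
            if ff >= threshold and fr >= threshold:
                calls.append(
                    SnpCall(pos, ref_base, alt, ff, fr,
                            (nf + nr) / (df + dr), nf + nr)
                )
    calls.sort(key=lambda c: (c.cdna_position, c.alt_base))
    return calls


# ---------------------------------------------------------------------------
# detector 1: gap runs in semi-global alignments
# ---------------------------------------------------------------------------

def detect_indels_gapped(
    alignments: list[Alignment],
    ref_offset: int = 1,
    min_length: int = 1,
) -> list[IndelCandidate]:
    """Every gap run in any alignment becomes a candidate; identical events merge."""
    support: dict[tuple, set[str]] = {}
    for aln in alignments:
        pos = aln.ref_start + ref_offset - 1
        qi = 0
        for op, length in aln.ops:
            if op == "M":
                pos += length
                qi += length
            elif op == "D":
                if length >= min_length:
                    key = ("deletion", pos, pos + length - 1, "")
                    support.setdefault(key, set()).add(aln.read_id)
                pos += length
            else:  # I
                seq = aln.query[qi : qi + length].upper()
                if length >= min_length:
                    key = ("insertion", pos - 1, pos - 1, seq)
                    support.setdefault(key, set()).add(aln.read_id)
                qi += length
    return [
        IndelCandidate(k[0], k[1], k[2], k[3], frozenset(ids), detector="gapped")
        for k, ids in sorted(support.items())
    ]


# ---------------------------------------------------------------------------
# detector 2: seed-and-extend split-read scan
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    q_start: int  # 0-based inclusive
    q_end: int    # 0-based inclusive
    diag: int     # r_start - q_start (0-based)

    @property
    def r_start(self) -> int:
        return self.q_start + self.diag

    @property
    def r_end(self) -> int:
        return self.q_end + self.diag

    @property
    def length(self) -> int:
        return self.q_end - self.q_start + 1


def _exact_blocks(read_seq: str, index: dict[str, list[int]], k: int) -> list[_Block]:
    """Maximal runs of co-diagonal exact k-mer anchors."""
    by_diag: dict[int, list[int]] = {}
    for i in range(len(read_seq) - k + 1):
        for j in index.get(read_seq[i : i + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    blocks: list[_Block] = []
    for diag, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for s in starts[1:]:
            if s > prev + 1:
                blocks.append(_Block(run_start, prev + k - 1, diag))
                run_start = s
            prev = s
        blocks.append(_Block(run_start, prev + k - 1, diag))
    return blocks


def build_kmer_index(reference: str, k: int = 11, max_hits: int = 4) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    ref = reference.upper()
    for j in range(len(ref) - k + 1):
        index.setdefault(ref[j : j + k], []).append(j)
    return {km: pos for km, pos in index.items() if len(pos) <= max_hits}


def detect_indels_splitread(
    reads: list[Read],
    reference: str,
    ref_offset: int = 1,
    seed_length: int = 11,
    min_block: int = 20,
    index: dict[str, list[int]] | None = None,
) -> list[IndelCandidate]:
    """Breakpoint detection from two-block chains of exact seed matches.

    A read whose best chain is two collinear blocks (each >= ``min_block``)
    separated by a reference gap with query-adjacent blocks yields a
    deletion; separated by unaligned query sequence with reference-adjacent
    blocks, an insertion carrying that sequence. Single-block reads yield
    nothing. Block overlaps from junction micro-homology are trimmed off
    the downstream block before breakpoints are read off.
    """
    ref = reference.upper()
    if index is None:
        index = build_kmer_index(ref, seed_length)
    support: dict[tuple, set[str]] = {}
    cache: dict[str, tuple | None] = {}
    for read in reads:
        seq = read.sequence.upper()
        if seq in cache:
            if cache[seq] is not None:
                support.setdefault(cache[seq], set()).add(read.id)
            continue
        cache[seq] = None
        blocks = [b for b in _exact_blocks(seq, index, seed_length) if b.length >= min_block]
        if len(blocks) < 2:
            continue
        blocks.sort(key=lambda b: (-b.length, b.q_start))
        b1 = blocks[0]
        partner = None
        for b2 in blocks[1:]:
            if b2.diag == b1.diag:
                continue
            if (b2.q_start > b1.q_start) == (b2.r_start > b1.r_start):
                partner = b2
                break
        if partner is None:
            continue
        left, right = (b1, partner) if b1.q_start <= partner.q_start else (partner, b1)
        overlap = max(left.q_end - right.q_start + 1,   # micro-homology may
                      left.r_end - right.r_start + 1)   # overlap in read or reference
        if overlap > 0:  # trim the downstream block
            right = _Block(right.q_start + overlap, right.q_end, right.diag)
            if right.length < min_block:
                continue
        q_gap = right.q_start - left.q_end - 1
        r_gap = right.r_start - left.r_end - 1
        if r_gap > 0 and q_gap == 0:
            key = ("deletion", left.r_end + ref_offset + 1, right.r_start + ref_offset - 1, "")
        elif q_gap > 0 and r_gap == 0:
            anchor = left.r_end + ref_offset  # cDNA position of last base before insert
            key = ("insertion", anchor, anchor, seq[left.q_end + 1 : right.q_start])
        else:
            continue
        cache[seq] = key
        support.setdefault(key, set()).add(read.id)
    return [
        IndelCandidate(k[0], k[1], k[2], k[3], frozenset(ids), detector="splitread")
        for k, ids in sorted(support.items())
    ]


# ---------------------------------------------------------------------------
# normalization and cross-validation
# ---------------------------------------------------------------------------

def equivalent_placements(candidate: IndelCandidate, reference: str) -> list[IndelCandidate]:
    """All sequence-equivalent placements of an indel, left to right.

    A deletion [s, e] shifts left while ref[s-1] == ref[e] and right while
    ref[e+1] == ref[s]; an insertion shifts by rotating its sequence
    through matching flanking bases.
    """
    ref = reference.upper()
    out = []
    if candidate.kind == "deletion":
        s, e = candidate.start, candidate.end
        while s > 1 and ref[s - 2] == ref[e - 1]:
            s, e = s - 1, e - 1
        placements = [(s, e)]
        while e < len(ref) and ref[e] == ref[s - 1]:
            s, e = s + 1, e + 1
            placements.append((s, e))
        out = [
            IndelCandidate("deletion", s, e, "", candidate.read_ids, candidate.detector)
            for s, e in placements
        ]
    else:
        a, seq = candidate.start, candidate.seq
        while a > 0 and seq[-1] == ref[a - 1]:
            a, seq = a - 1, ref[a - 1] + seq[:-1]
        placements = [(a, seq)]
        while a < len(ref) and seq[0] == ref[a]:
            a, seq = a + 1, seq[1:] + ref[a]
            placements.append((a, seq))
        out = [
            IndelCandidate("insertion", a, a, s, candidate.read_ids, candidate.detector)
            for a, s in placements
        ]
    return out


def normalize_indel(candidate: IndelCandidate, model: TranscriptModel) -> IndelCandidate:
    """Canonical placement: prefer exon-boundary breakpoints, else leftmost.

    Among all sequence-equivalent placements, a placement whose breakpoints
    coincide with an exon boundary of the model (deletion starting at an
    exon start or ending at an exon end; insertion anchored at an exon end)
    is chosen; ties and the no-boundary case resolve to the leftmost.
    """
    placements = equivalent_placements(candidate, model.cdna_seq)
    starts, ends = model.exon_starts, model.exon_ends
    for p in placements:  # placements are ordered leftmost -> rightmost
        if p.kind == "deletion" and (p.start in starts or p.end in ends):
            return p
        if p.kind == "insertion" and p.start in ends:
            return p
    return placements[0]


def cross_validate(
    gapped: list[IndelCandidate],
    splitread: list[IndelCandidate],
    coverage=None,
) -> list[IndelCall]:
    """Intersect the two detectors' normalized candidate sets.

    Events present in both (exact kind/coordinates/sequence match after
    normalization) become :class:`IndelCall`\\ s with pooled read support;
    no frequency floor is applied. ``coverage`` may be a callable
    ``pos -> covering reads`` used to fill in the frequency.
    """
    by_key = {c.key: c for c in gapped}
    calls: list[IndelCall] = []
    for sc in splitread:
        gc = by_key.get(sc.key)
        if gc is None:
            continue
        ids = gc.read_ids | sc.read_ids
        freq = float("nan")
        if coverage is not None:
            cov = coverage(sc.start)
            freq = len(ids) / cov if cov else float("nan")
        calls.append(IndelCall(
            IndelCandidate(sc.kind, sc.start, sc.end, sc.seq, frozenset(ids), "both"),
            frozenset(ids), frequency=freq,
        ))
    calls.sort(key=lambda c: (c.start, c.kind, c.seq))
    return calls


def merge_candidates(cands: list[IndelCandidate]) -> list[IndelCandidate]:
    """Merge candidates sharing a key, pooling read support."""
    merged: dict[tuple, set[str]] = {}
    det: dict[tuple, str] = {}
    for c in cands:
        merged.setdefault(c.key, set()).update(c.read_ids)
        det[c.key] = c.detector
    return [
        IndelCandidate(k[0], k[1], k[2], k[3], frozenset(ids), det[k])
        for k, ids in sorted(merged.items())
    ]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def build_indel_consensus(
    call: IndelCall,
    reads_by_id: dict[str, Read],
    reference: str,
    ref_offset: int = 1,
    flank: int = 25,
) -> str:
    """Per-column majority of supporting reads over the event +/- flank.

    The variant-allele template (reference flanks around the event, with
    the insertion spliced in / the deletion excised) is located in each
    supporting read by infix alignment; columns are voted by majority with
    ties resolved to the template base.
    """
    if not call.read_ids:
        raise ValueError("indel call without supporting reads")
    ref = reference.upper()
    s = call.start - ref_offset  # 0-based
    e = call.end - ref_offset
    if call.kind == "deletion":
        template = ref[max(0, s - flank) : s] + ref[e + 1 : e + 1 + flank]
    else:
        template = ref[max(0, s + 1 - flank) : s + 1] + call.seq + ref[s + 1 : s + 1 + flank]
    votes = [dict() for _ in template]
    for rid in sorted(call.read_ids):
        read = reads_by_id.get(rid)
        if read is None:
            continue
        res = edlib.align(template, read.sequence.upper(), mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        start = res["locations"][0][0]
        ti = 0
        qi = start
        for n, op in _parse_cigar(res["cigar"]):
            if op == "=" or op == "X" or op == "M":
                for _ in range(n):
                    votes[ti][read.sequence[qi].upper()] = votes[ti].get(read.sequence[qi].upper(), 0) + 1
                    ti += 1
                    qi += 1
            elif op == "I":  # in template, missing from read
                ti += n
            else:  # op == "D": extra read bases
                qi += n
    out = []
    for col, ref_base in zip(votes, template):
        if not col:
            out.append(ref_base)
            continue
        best = max(col.values())
        winners = sorted(b for b, n in col.items() if n == best)
        out.append(ref_base if ref_base in winners else winners[0])
    return "".join(out)


def _parse_cigar(cigar: str):
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            yield n, ch
            n = 0
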