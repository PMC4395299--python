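"""Synthetic transcript fixtures and 454-style amplicon read simulation.

The generator emulates the study conditions of kinase-domain amplicon
ultra-deep sequencing: per-sample depth drawn from a truncated normal
(mean 2234, sd 734 reads), reads split between forward and reverse strands,
variants injected as whole haplotypes at controlled target frequencies,
MID barcode prefixes, and an optional simplified 454 error model (uniform
substitutions plus homopolymer-biased 1-nt indels). Every simulation
returns a machine-readable truth table of realized per-strand counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_processing import Read, revcomp
from .transcript import (
    ACCEPTOR,
    DONOR,
    ExonRecord,
    ModelError,
    TranscriptModel,
    build_transcript_model,
)

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class GenerationError(RuntimeError):
    """Constraints could not be satisfied within bounded retries."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# variant specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """One variant haplotype to inject at a target allele frequency.

    Coordinates are 1-based inclusive cDNA positions. Insertions sit
    between ``anchor`` and ``anchor + 1``.
    """

    kind: str  # snp | deletion | insertion
    target_frequency: float
    pos: int = 0            # snp
    alt: str = ""           # snp
    start: int = 0          # deletion
    end: int = 0            # deletion
    anchor: int = 0         # insertion
    seq: str = ""           # insertion
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "deletion", "insertion"):
            raise ConfigError(f"unknown variant kind {self.kind!r}")
        if not 0 < self.target_frequency <= 1:
            raise ConfigError("target_frequency must be in (0, 1]")

    @staticmethod
    def snp(pos: int, alt: str, freq: float, label: str = "") -> "VariantSpec":
        return VariantSpec("snp", freq, pos=pos, alt=alt.upper(),
                           label=label or f"c.{pos}>{alt.upper()}")

    @staticmethod
    def deletion(start: int, end: int, freq: float, label: str = "") -> "VariantSpec":
        return VariantSpec("deletion", freq, start=start, end=end,
                           label=label or f"c.{start}-{end}del")

    @staticmethod
    def insertion(anchor: int, seq: str, freq: float, label: str = "") -> "VariantSpec":
        return VariantSpec("insertion", freq, anchor=anchor, seq=seq.upper(),
                           label=label or f"c.{anchor + 1}ins{len(seq)}")

    @staticmethod
    def intron_retention(
        model: TranscriptModel,
        downstream_exon_id: str,
        length: int,
        freq: float,
        side: str = "3prime",
        label: str = "",
    ) -> "VariantSpec":
        """Partial retention of the intron preceding/following an exon junction.

        ``side="3prime"`` retains the terminal ``length`` bases of the
        intron upstream of ``downstream_exon_id`` (alternative 3' splice
        site); ``side="5prime"`` retains the initial ``length`` bases of
        the intron downstream of that exon's predecessor (alternative 5'
        splice site). Both insert at the same exon junction.
        """
        exon = model.exon_by_id(downstream_exon_id)
        anchor = exon.cdna_start - 1
        if side == "3prime":
            flank = exon.upstream_intron_seq
            if length > len(flank):
                raise ConfigError("retention longer than stored intron flank")
            seq = flank[-length:]
        elif side == "5prime":
            prev = model.exon_of(anchor)
            flank = prev.downstream_intron_seq
            if length > len(flank):
                raise ConfigError("retention longer than stored intron flank")
            seq = flank[:length]
        else:
            raise ConfigError("side must be '3prime' or '5prime'")
        return VariantSpec.insertion(anchor, seq, freq,
                                     label=label or f"c.{anchor + 1}ins{length}")

    def validate(self, model: TranscriptModel) -> None:
        L = len(model.cdna_seq)
        if self.kind == "snp":
            if not 1 <= self.pos <= L:
                raise ConfigError(f"SNP position {self.pos} out of bounds")
            if self.alt == model.cdna_seq[self.pos - 1]:
                raise ConfigError("SNP alt equals reference base")
            if self.alt not in "ACGT":
                raise ConfigError(f"bad alt base {self.alt!r}")
        elif self.kind == "deletion":
            if not 1 <= self.start <= self.end <= L:
                raise ConfigError(f"deletion {self.start}-{self.end} out of bounds")
        else:
            if not 1 <= self.anchor < L:
                raise ConfigError(f"insertion anchor {self.anchor} out of bounds")
            if not self.seq:
                raise ConfigError("insertion sequence empty")


def apply_variant(model: TranscriptModel, spec: VariantSpec | None) -> str:
    """Return the full variant cDNA haplotype sequence (``None`` -> WT)."""
    seq = model.cdna_seq
    if spec is None:
        return seq
    if spec.kind == "insertion" and not spec.seq:
        return seq  # empty insertion is the identity
    spec.validate(model)
    if spec.kind == "snp":
        return seq[: spec.pos - 1] + spec.alt + seq[spec.pos :]
    if spec.kind == "deletion":
        return seq[: spec.start - 1] + seq[spec.end :]
    return seq[: spec.anchor] + spec.seq + seq[spec.anchor :]


def _apply_to_interval(model: TranscriptModel, spec: VariantSpec | None,
                       start: int, end: int) -> str:
    """Variant haplotype restricted to the WT amplicon interval [start, end]."""
    wt = model.cdna_seq[start - 1 : end]
    if spec is None:
        return wt
    if spec.kind == "snp":
        if not start <= spec.pos <= end:
            raise ConfigError(f"SNP at {spec.pos} outside amplicon {start}-{end}")
        i = spec.pos - start
        return wt[:i] + spec.alt + wt[i + 1 :]
    if spec.kind == "deletion":
        if not (start <= spec.start and spec.end <= end):
            raise ConfigError("deletion not contained in amplicon")
        return wt[: spec.start - start] + wt[spec.end - start + 1 :]
    if not start <= spec.anchor < end:
        raise ConfigError("insertion anchor outside amplicon")
    i = spec.anchor - start + 1
    return wt[:i] + spec.seq + wt[i:]


# ---------------------------------------------------------------------------
# simulation config / truth table
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-condition defaults: depth 2234 +/- 734 reads, even strand split."""

    depth_mean: float = 2234.0
    depth_sd: float = 734.0
    strand_fraction: float = 0.5
    per_base_error: float = 0.0
    homopolymer_indel_rate: float = 0.0
    amplicons: list[tuple[int, int]] | None = None  # None -> one full-length amplicon
    mid_length: int = 10
    quality_char: str = "I"

    def __post_init__(self) -> None:
        for p in (self.strand_fraction, self.per_base_error, self.homopolymer_indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        d = asdict(self)
        if seed is not None:
            d["seed"] = seed
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass
class SampleReadSet:
    sample_id: str
    mid: str
    reads: list[Read]


class TruthTable:
    """Realized per-variant read counts and frequencies for one sample."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record(self, sample: str, amplicon: tuple[int, int], spec: VariantSpec | None,
               n_fwd: int, n_rev: int, depth: int) -> None:
        label = spec.label if spec is not None else "WT"
        self.rows.append(
            {
                "sample": sample,
                "amplicon_start": amplicon[0],
                "amplicon_end": amplicon[1],
                "variant": label,
                "kind": spec.kind if spec else "wt",
                "target_frequency": spec.target_frequency if spec else float("nan"),
                "n_fwd": n_fwd,
                "n_rev": n_rev,
                "depth": depth,
                "realized_frequency": (n_fwd + n_rev) / depth if depth else 0.0,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def realized(self, label: str, sample: str | None = None) -> dict:
        for row in self.rows:
            if row["variant"] == label and (sample is None or row["sample"] == sample):
                return row
        raise KeyError(label)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_intron_flank(rng: np.random.Generator, length: int, role: str) -> str:
    flank = "".join(rng.choice(list("ACGT"), size=length))
    if role == "donor":
        return DONOR + flank[2:]
    return flank[:-2] + ACCEPTOR


def generate_reference(
    seed: int | np.random.Generator,
    exon_lengths: list[int],
    intron_flank_length: int = 150,
    exon_ids: list[str] | None = None,
    engineered_codons: dict[int, str] | None = None,
    name: str = "synthetic-transcript",
) -> TranscriptModel:
    """Random transcript fixture with canonical GT/AG intron flanks.

    The CDS spans the whole cDNA (c.1 = ATG); ``sum(exon_lengths)`` must be
    a multiple of 3 and includes the stop codon, which is fixed to TAA.
    Codons are drawn from the 61 sense codons so no internal stop can
    occur; ``engineered_codons`` (1-based codon number -> triplet) lets a
    fixture pin specific residues.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if any(l <= 0 for l in exon_lengths):
        raise GenerationError("exon lengths must be positive")
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise GenerationError(f"total cDNA length {total} not a multiple of 3")
    n_codons = total // 3
    if n_codons < 2:
        raise GenerationError("need at least start + stop codon")
    codons = ["ATG"] + [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 2)] + ["TAA"]
    for num, triplet in (engineered_codons or {}).items():
        if not 1 <= num <= n_codons - 1:
            raise GenerationError(f"engineered codon {num} out of range")
        if triplet.upper() in ("TAA", "TAG", "TGA"):
            raise GenerationError("engineered codon is a stop codon")
        codons[num - 1] = triplet.upper()
    cdna = "".join(codons)

    if exon_ids is None:
        exon_ids = [str(i + 1) for i in range(len(exon_lengths))]
    exons = []
    pos = 1
    for i, (eid, length) in enumerate(zip(exon_ids, exon_lengths)):
        up = "" if i == 0 else _random_intron_flank(rng, intron_flank_length, "acceptor")
        down = "" if i == len(exon_lengths) - 1 else _random_intron_flank(rng, intron_flank_length, "donor")
        exons.append(ExonRecord(eid, pos, pos + length - 1, up, down))
        pos += length
    return build_transcript_model(exons, cdna, n_codons - 1, name=name)


# Engineered residues of the kinase-domain fixture. Pinning these codons
# makes the fixture reproduce the study's residue identities at the
# annotated positions (S232, F234, P276, R291, R308, D309, R335, Y664; the
# silent-SNP third-position sites; and the hybrid codons produced by the
# exon-skip / junction deletions).
_KD_CODONS = {
    1: "ATG",
    232: "AGC",  # S, spans the exon 22/23 junction (c.694-696)
    234: "TTC",  # F (c.700-702)
    249: "ACC",  # third position c.747 = C (C>T silent)
    275: "GCG",  # third position c.825 = G (G>A silent); exon 23 3' end
    276: "CCT",  # P at exon 24 start (c.826-828)
    291: "CGA",  # R; c.872 G>A -> CAA (Q)
    298: "GGG",  # third position c.894 = G (G>A silent)
    303: "TCC",  # third position c.909 = C (C>T silent)
    308: "CGA",  # R, spans the exon 24/25 junction (c.922-924)
    309: "GAC",  # D (c.925-927)
    310: "ACC",  # keeps the post c.923-924del frame encoding H at residue 309
    325: "GTG",  # third position c.975 = G (G>A silent)
    335: "CGA",  # R; c.1004 G>A -> CAA (Q)
    664: "TAC",  # Y (c.1990-1992)
}

#: default amplicon over the kinase-domain region of the fixture; flanks of
#: ~150 nt around the variant-bearing exons keep splice-sized deletions
#: representable in the affine-gap alignment
KD_AMPLICON = (550, 1100)


def _retained_frames_clean(flank: str, lengths=(24, 36)) -> bool:
    # retained segments are inserted between codon offsets 2 and 3 of the
    # junction codon; reject flanks whose in-frame retentions create stops
    for k in lengths:
        ins = flank[-k:]
        codons = [ins[i : i + 3] for i in range(1, k - 2, 3)]
        codons.append(ins[k - 2 :] + "A")  # closing hybrid codon (c.924 = A)
        if any(c in ("TAA", "TAG", "TGA") for c in codons):
            return False
    return True


def alk_like_model(seed: int = 7, intron_flank_length: int = 150) -> TranscriptModel:
    """The kinase-domain fixture: 2043-nt cDNA, 680-aa WT protein.

    Exon geometry mirrors the sequenced fusion transcript: the exon-23
    analog spans c.696-825 (130 nt), exon 24 c.826-923 (98 nt), exon 25
    starts at c.924. The 3' flank of the intron-24 analog is constrained so
    the 24/36/106-nt retention haplotypes behave like the observed splice
    variants (in-frame insertions stay stop-free; the 106-nt retention
    shifts the frame through an engineered His codon at residue 309).
    """
    rng = np.random.default_rng(seed)
    model = generate_reference(
        rng,
        exon_lengths=[695, 130, 98, 1120],
        intron_flank_length=intron_flank_length,
        exon_ids=["22", "23", "24", "25"],
        engineered_codons=_KD_CODONS,
        name="kd-fusion-fixture",
    )
    if intron_flank_length < 106:
        return model
    # rebuild the intron-24 3' flank under retention constraints
    for _ in range(1000):
        flank = _random_intron_flank(rng, intron_flank_length, "acceptor")
        flank = flank[:-106] + "G" + "CAC" + flank[-102:]
        if _retained_frames_clean(flank):
            break
    else:  # pragma: no cover
        raise GenerationError("could not satisfy intron-retention constraints")
    exons = list(model.exons)
    e25 = exons[3]
    exons[3] = ExonRecord(e25.exon_id, e25.cdna_start, e25.cdna_end,
                          upstream_intron_seq=flank,
                          downstream_intron_seq=e25.downstream_intron_seq)
    return build_transcript_model(exons, model.cdna_seq, model.wt_protein_length,
                                  name=model.name)


# ---------------------------------------------------------------------------
# MIDs and error model
# ---------------------------------------------------------------------------

def make_mids(n: int, rng: np.random.Generator, length: int = 10, min_dist: int = 3) -> list[str]:
    """Synthetic MID barcodes with pairwise Hamming distance >= min_dist."""
    mids: list[str] = []
    for _ in range(10000):
        cand = "".join(rng.choice(list("ACGT"), size=length))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_dist for m in mids):
            mids.append(cand)
            if len(mids) == n:
                return mids
    raise GenerationError(f"could not build {n} MIDs at distance {min_dist}")


def _homopolymer_runs(seq: str, min_run: int = 3) -> list[tuple[int, int]]:
    runs, i = [], 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def apply_sequencing_errors(
    seq: str,
    rng: np.random.Generator,
    per_base_error: float = 0.0,
    homopolymer_indel_rate: float = 0.0,
) -> str:
    """Uniform substitutions plus homopolymer-biased 1-nt indels."""
    s = list(seq)
    if per_base_error > 0:
        hits = np.nonzero(rng.random(len(s)) < per_base_error)[0]
        for i in hits:
            s[i] = str(rng.choice([b for b in "ACGT" if b != s[i]]))
    if homopolymer_indel_rate > 0:
        out = "".join(s)
        edits = []
        for start, stop in _homopolymer_runs(out):
            if rng.random() < homopolymer_indel_rate:
                edits.append((start, stop, rng.random() < 0.5))
        for start, stop, is_ins in reversed(edits):
            if is_ins:
                out = out[:stop] + out[start] + out[stop:]
            else:
                out = out[:start] + out[start + 1 :]
        return out
    return "".join(s)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def simulate_sample(
    model: TranscriptModel,
    variant_specs: list[VariantSpec],
    config: SimulationConfig,
    rng: int | np.random.Generator,
    sample_id: str = "S1",
    mid: str = "",
) -> tuple[SampleReadSet, TruthTable]:
    """Draw one sample's reads from the WT + variant haplotype mixture.

    Per amplicon, depth ~ round(Normal(mean, sd)) truncated at >= 1; each
    read picks a haplotype multinomially at the target frequencies and a
    strand (reverse reads are emitted reverse-complemented); errors are
    applied after the haplotype choice; the MID prefix is attached last.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for spec in variant_specs:
        spec.validate(model)
    total_alt = sum(s.target_frequency for s in variant_specs)
    if total_alt > 1.0 + 1e-12:
        raise ConfigError(f"variant frequencies sum to {total_alt} > 1")
    amplicons = config.amplicons or [(1, len(model.cdna_seq))]
    probs = [1.0 - total_alt] + [s.target_frequency for s in variant_specs]
    haps: list[VariantSpec | None] = [None] + list(variant_specs)

    truth = TruthTable()
    reads: list[Read] = []
    for amp in amplicons:
        depth = max(1, int(round(rng.normal(config.depth_mean, config.depth_sd))))
        counts = rng.multinomial(depth, probs)
        for spec, n_hap in zip(haps, counts):
            hap_seq = _apply_to_interval(model, spec, amp[0], amp[1])
            n_fwd = int(rng.binomial(n_hap, config.strand_fraction))
            truth.record(sample_id, amp, spec, n_fwd, int(n_hap) - n_fwd, depth)
            label = spec.label if spec else "WT"
            for k in range(int(n_hap)):
                strand = "+" if k < n_fwd else "-"
                seq = apply_sequencing_errors(
                    hap_seq, rng, config.per_base_error, config.homopolymer_indel_rate
                )
                if strand == "-":
                    seq = revcomp(seq)
                seq = mid + seq
                rid = f"{sample_id}:a{amp[0]}-{amp[1]}:{label}:{strand}:{k}"
                reads.append(Read(rid, seq, qualities=config.quality_char * len(seq)))
    return SampleReadSet(sample_id, mid, reads), truth


def simulate_cohort(
    model: TranscriptModel,
    sample_variants: dict[str, list[VariantSpec]],
    config: SimulationConfig,
    seed: int,
) -> tuple[list[SampleReadSet], dict[str, str], pd.DataFrame]:
    """Simulate several MID-tagged samples; returns (read sets, MID table, truth)."""
    rng = np.random.default_rng(seed)
    mids = make_mids(len(sample_variants), rng, length=config.mid_length)
    mid_table = dict(zip(sample_variants, mids))
    read_sets, truths = [], []
    for sample_id, specs in sample_variants.items():
        rs, truth = simulate_sample(model, specs, config, rng,
                                    sample_id=sample_id, mid=mid_table[sample_id])
        read_sets.append(rs)
        truths.append(truth.to_frame())
    return read_sets, mid_table, pd.concat(truths, ignore_index=True)


def write_fastq(reads: list[Read], path: str | Path, default_quality: str = "I") -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        quals = r.qualities or default_quality * len(r.sequence)
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
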