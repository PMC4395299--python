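"""End-to-end orchestration: simulate/load -> demultiplex -> orient ->
align -> pileup -> call -> cross-validate -> classify -> annotate -> report.

Samples are processed independently and merged afterwards by normalized
variant identity, so the pooled table mirrors per-patient detection counts
and frequency ranges. Every run is deterministic given its seed and writes
a provenance JSON recording all effective parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, read_processing as rp
from .annotate import (
    ProteinConsequence,
    SpliceClass,
    UnsupportedVariantError,
    annotate_indel,
    annotate_snp,
    classify_splice_event,
)
from .calling import IndelCall, SnpCall
from .simulate import SimulationConfig, VariantSpec, simulate_cohort, write_fastq
from .transcript import TranscriptModel

logger = logging.getLogger("deepamp")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``reads_path`` (FASTQ, pre-pooled multi-sample run) or
    ``sample_variants`` (simulation request) must be provided.
    """

    model_path: str | None = None
    reads_path: str | None = None
    mid_table: dict[str, str] | None = None
    sample_variants: dict[str, list[VariantSpec]] | None = None
    simulation: SimulationConfig | None = None
    snp_threshold: float = calling.SNP_THRESHOLD
    amplicon: tuple[int, int] | None = None
    seed: int = 0
    min_block: int = 20
    seed_length: int = 11
    scoring: rp.Scoring = field(default_factory=rp.Scoring)

    def __post_init__(self) -> None:
        if not 0 < self.snp_threshold < 1:
            raise ValueError("snp_threshold must lie in (0, 1)")
        if (self.reads_path is None) == (self.sample_variants is None):
            raise ValueError("provide exactly one of reads_path or sample_variants")


@dataclass
class AnnotatedVariant:
    sample: str
    label: str
    variant_type: str  # snp | deletion | insertion
    description: str
    consequence: ProteinConsequence | None
    frequency: float
    n_supporting: int


@dataclass
class PipelineResult:
    table: pd.DataFrame
    per_sample: dict[str, list[AnnotatedVariant]]
    log: list[str]


# ---------------------------------------------------------------------------
# per-sample work
# ---------------------------------------------------------------------------

def process_sample(
    sample_id: str,
    reads: list[rp.Read],
    model: TranscriptModel,
    amplicon: tuple[int, int],
    snp_threshold: float,
    scoring: rp.Scoring,
    seed_length: int = 11,
    min_block: int = 20,
    log: list[str] | None = None,
) -> tuple[list[SnpCall], list[tuple[IndelCall, SpliceClass]], rp.Pileup]:
    """Run the per-sample calling stack on demultiplexed, MID-trimmed reads."""
    log = log if log is not None else []
    a0, a1 = amplicon
    ref = model.cdna_seq[a0 - 1 : a1]
    oriented, bad = rp.orient_reads(reads, ref)
    if bad:
        log.append(f"{sample_id}: {len(bad)} unalignable reads dropped")
    alignments = rp.align_reads(oriented, ref, scoring)
    pileup = rp.build_pileup(alignments, ref, ref_offset=a0)
    snps = calling.call_snps(pileup, ref, threshold=snp_threshold, log=log)

    gapped = [calling.normalize_indel(c, model)
              for c in calling.detect_indels_gapped(alignments, ref_offset=a0)]
    split = [calling.normalize_indel(c, model)
             for c in calling.detect_indels_splitread(
                 oriented, ref, ref_offset=a0,
                 seed_length=seed_length, min_block=min_block)]
    calls = calling.cross_validate(
        calling.merge_candidates(gapped), calling.merge_candidates(split),
        coverage=pileup.coverage,
    )
    reads_by_id = {r.id: r for r in oriented}
    annotated = []
    for call in calls:
        call.consensus_seq = calling.build_indel_consensus(
            call, reads_by_id, ref, ref_offset=a0)
        annotated.append((call, classify_splice_event(call, model)))
    return snps, annotated, pileup


def _annotate_sample(
    sample_id: str,
    snps: list[SnpCall],
    indels: list[tuple[IndelCall, SpliceClass]],
    model: TranscriptModel,
    log: list[str],
) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    for snp in snps:
        try:
            cons = annotate_snp(snp, model)
            desc = f"{cons.kind} point mutation"
        except UnsupportedVariantError as exc:
            cons, desc = None, f"unsupported substitution ({exc})"
            log.append(f"{sample_id}: {snp.label}: {exc}")
        out.append(AnnotatedVariant(sample_id, snp.label, "snp", desc, cons,
                                    snp.freq_overall, snp.n_supporting))
    for call, splice in indels:
        try:
            cons = annotate_indel(call, model)
        except UnsupportedVariantError as exc:
            cons = None
            log.append(f"{sample_id}: {call.label}: {exc}")
        out.append(AnnotatedVariant(sample_id, call.label, call.kind,
                                    splice.describe(), cons,
                                    call.frequency, len(call.read_ids)))
    return out


# ---------------------------------------------------------------------------
# run + report
# ---------------------------------------------------------------------------

def _format_pct(f: float) -> str:
    return f"{100 * f:.2g}%"


def merge_variant_table(per_sample: dict[str, list[AnnotatedVariant]]) -> pd.DataFrame:
    """Pool per-sample variants by identity into the report table."""
    n_samples = len(per_sample)
    pooled: dict[tuple, dict] = {}
    for sample, variants in per_sample.items():
        for v in variants:
            key = (v.label, v.description)
            entry = pooled.setdefault(key, {
                "cDNA variant": v.label,
                "Description": v.description,
                "Protein change": v.consequence.name if v.consequence else "?",
                "Amino Acids": v.consequence.protein_length if v.consequence else pd.NA,
                "samples": set(),
                "freqs": [],
            })
            entry["samples"].add(sample)
            entry["freqs"].append(v.frequency)
    rows = []
    for entry in pooled.values():
        freqs = sorted(f for f in entry["freqs"] if f == f)
        if not freqs:
            freq_str = "NA"
        elif len(freqs) == 1 or _format_pct(freqs[0]) == _format_pct(freqs[-1]):
            freq_str = _format_pct(freqs[-1])
        else:
            freq_str = f"{_format_pct(freqs[0])}–{_format_pct(freqs[-1])}"
        rows.append({
            "cDNA variant": entry["cDNA variant"],
            "Description": entry["Description"],
            "Protein change": entry["Protein change"],
            "Amino Acids": entry["Amino Acids"],
            "Patients": f"{len(entry['samples'])}/{n_samples}",
            "Frequency": freq_str,
        })
    cols = ["cDNA variant", "Description", "Protein change",
            "Amino Acids", "Patients", "Frequency"]
    df = pd.DataFrame(rows, columns=cols)
    if not df.empty:
        df = df.sort_values("cDNA variant", kind="stable").reset_index(drop=True)
    return df


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    """UTF-8 TSV with stable column order; header-only when empty."""
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_vcf(
    sample_id: str,
    model: TranscriptModel,
    snps: list[SnpCall],
    indels: list[tuple[IndelCall, SpliceClass]],
    path: str | Path,
) -> None:
    """Per-sample VCF with the cDNA as the contig (pysam-backed)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={model.name},length={len(model.cdna_seq)}>")
    header.add_line('##INFO=<ID=FF,Number=1,Type=Float,Description="Forward-strand allele frequency">')
    header.add_line('##INFO=<ID=FR,Number=1,Type=Float,Description="Reverse-strand allele frequency">')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Overall allele frequency">')
    header.add_line('##INFO=<ID=NS,Number=1,Type=Integer,Description="Supporting reads">')
    header.add_line('##INFO=<ID=DETECTORS,Number=1,Type=String,Description="INDEL detector support">')
    header.add_line('##INFO=<ID=SPLICE,Number=1,Type=String,Description="Splice classification">')
    ref = model.cdna_seq
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        records = []
        for s in snps:
            records.append((s.cdna_position, s.ref_base, s.alt_base, {
                "FF": s.freq_forward, "FR": s.freq_reverse,
                "AF": s.freq_overall, "NS": s.n_supporting}))
        for call, splice in indels:
            info = {"AF": call.frequency, "NS": len(call.read_ids),
                    "DETECTORS": "gapped+splitread",
                    "SPLICE": splice.category}
            if call.kind == "deletion":
                pos = call.start - 1
                records.append((pos, ref[pos - 1 : call.end], ref[pos - 1], info))
            else:
                pos = call.start
                records.append((pos, ref[pos - 1], ref[pos - 1] + call.seq, info))
        for pos, r, a, info in sorted(records, key=lambda t: t[0]):
            rec = vcf.new_record(contig=model.name, start=pos - 1,
                                 alleles=(r, a))
            for k, v in info.items():
                if v == v:  # skip NaN
                    rec.info[k] = v
            vcf.write(rec)


def run_pipeline(
    config: PipelineConfig,
    model: TranscriptModel,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write artifacts to disk."""
    log: list[str] = [f"seed={config.seed}", f"snp_threshold={config.snp_threshold}",
                      f"scoring={config.scoring}",
                      f"seed_length={config.seed_length}", f"min_block={config.min_block}"]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.sample_variants is not None:
        sim = config.simulation or SimulationConfig()
        if config.amplicon is not None and sim.amplicons is None:
            sim.amplicons = [config.amplicon]
        read_sets, mid_table, truth = simulate_cohort(
            model, config.sample_variants, sim, config.seed)
        log.append(f"simulated {len(read_sets)} samples, "
                   f"depth_mean={sim.depth_mean}, depth_sd={sim.depth_sd}, "
                   f"per_base_error={sim.per_base_error}, "
                   f"homopolymer_indel_rate={sim.homopolymer_indel_rate}")
        pooled = [r for rs in read_sets for r in rs.reads]
        if out is not None:
            write_fastq(pooled, out / "reads.fastq")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        path = Path(config.reads_path)
        if not path.exists():
            raise IOError(f"unreadable reads path: {path}")
        pooled = rp.read_fastq(path)
        mid_table = config.mid_table or {}
        log.append(f"loaded {len(pooled)} reads from {path}")

    if not mid_table:
        raise ValueError("a MID table is required for demultiplexing")
    demux = rp.demultiplex(pooled, mid_table)
    log.append(f"demultiplexed: {demux.counts}")

    amplicon = config.amplicon or (1, len(model.cdna_seq))
    per_sample: dict[str, list[AnnotatedVariant]] = {}
    for sample_id, reads in demux.by_sample.items():
        if not reads:
            log.append(f"{sample_id}: empty read set, reporting no variants")
            per_sample[sample_id] = []
            continue
        snps, indels, _ = process_sample(
            sample_id, reads, model, amplicon,
            config.snp_threshold, config.scoring,
            config.seed_length, config.min_block, log)
        per_sample[sample_id] = _annotate_sample(sample_id, snps, indels, model, log)
        if out is not None:
            write_vcf(sample_id, model, snps, indels, out / f"{sample_id}.vcf")

    table = merge_variant_table(per_sample)
    if out is not None:
        write_report(table, out / "variant_table.tsv")
        (out / "provenance.json").write_text(json.dumps({
            "seed": config.seed,
            "snp_threshold": config.snp_threshold,
            "amplicon": list(amplicon),
            "scoring": vars(config.scoring),
            "seed_length": config.seed_length,
            "min_block": config.min_block,
            "mid_table": mid_table,
            "log": log,
        }, indent=1))
        (out / "run.log").write_text("\n".join(log) + "\n")
    for line in log:
        logger.info(line)
    return PipelineResult(table, per_sample, log)
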