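"""Splice-event classification and protein-consequence annotation.

Validated cDNA indels from an amplicon experiment on a mature mRNA are,
in this system, mostly footprints of alternative splicing: a deletion that
exactly removes complete exons is exon skipping; a deletion forming a
strict prefix/suffix of one exon is an alternative 3'/5' splice site; an
insertion at an exon junction whose sequence matches a terminal segment of
the adjacent intron is partial intron retention. Protein consequences
follow from the CDS frame: net length change = 0 mod 3 gives an in-frame
deletion/insertion with exact residue bookkeeping, anything else shifts
the frame and truncates at the first stop codon of the shifted frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .calling import IndelCall, SnpCall
from .transcript import CoordinateError, TranscriptModel

EN_DASH = "–"


class UnsupportedVariantError(ValueError):
    """Variant outside the modelled space (stop codon, CDS-end spanning)."""


@dataclass(frozen=True)
class SpliceClass:
    category: str  # exon_skipping | partial_exon_deletion_alt5ss | partial_exon_deletion_alt3ss | intron_retention_alt5ss | intron_retention_alt3ss | generic_indel
    exons_involved: tuple[str, ...] = ()
    donor_acceptor_ok: bool | None = None  # advisory GT/AG check at novel junctions

    def describe(self) -> str:
        """Human-readable description in the reporting style of the study."""
        ex = "".join(self.exons_involved) if len(self.exons_involved) < 2 else (
            self.exons_involved[0] + EN_DASH + self.exons_involved[-1]
        )
        return {
            "exon_skipping": f"exon {ex} skipping",
            "partial_exon_deletion_alt5ss": f"exon {ex} partial deletion, alternative 5' splice site",
            "partial_exon_deletion_alt3ss": f"exon {ex} partial deletion, alternative 3' splice site",
            "intron_retention_alt5ss": f"intron {ex} partial retention, alternative 5' splice site",
            "intron_retention_alt3ss": f"intron {ex} partial retention, alternative 3' splice site",
            "generic_indel": "indel",
        }[self.category]


@dataclass(frozen=True)
class ProteinConsequence:
    kind: str  # silent | missense | inframe_deletion | inframe_insertion | frameshift_oof
    name: str
    protein_length: int
    notes: str = ""


# ---------------------------------------------------------------------------
# splice classification
# ---------------------------------------------------------------------------

def classify_splice_event(call: IndelCall, model: TranscriptModel) -> SpliceClass:
    """Rule-based classifier of a normalized indel against the exon model."""
    L = len(model.cdna_seq)
    if call.kind == "deletion":
        if not (1 <= call.start <= call.end <= L):
            raise CoordinateError(f"deletion {call.label} outside transcript")
        first = model.exon_of(call.start)
        last = model.exon_of(call.end)
        if call.start == first.cdna_start and call.end == last.cdna_end:
            i = model.exons.index(first)
            j = model.exons.index(last)
            return SpliceClass("exon_skipping",
                               tuple(e.exon_id for e in model.exons[i : j + 1]))
        if first is last:
            if call.end == first.cdna_end and call.start > first.cdna_start:
                return SpliceClass("partial_exon_deletion_alt5ss", (first.exon_id,),
                                   donor_acceptor_ok=_donor_ok_at(model, call.start))
            if call.start == first.cdna_start and call.end < first.cdna_end:
                return SpliceClass("partial_exon_deletion_alt3ss", (first.exon_id,),
                                   donor_acceptor_ok=None)
        return SpliceClass("generic_indel")

    # insertion
    anchor = call.start
    if not 1 <= anchor < L:
        raise CoordinateError(f"insertion anchor {anchor} outside transcript")
    exon = model.exon_of(anchor)
    if anchor == exon.cdna_end:
        nxt = model.exon_of(anchor + 1)
        up_flank = nxt.upstream_intron_seq.upper()   # 3' end of the intron
        down_flank = exon.downstream_intron_seq.upper()  # 5' start of the intron
        ins = call.seq.upper()
        if up_flank and up_flank.endswith(ins):
            return SpliceClass("intron_retention_alt3ss", (exon.exon_id,),
                               donor_acceptor_ok=True)
        if down_flank and down_flank.startswith(ins):
            return SpliceClass("intron_retention_alt5ss", (exon.exon_id,),
                               donor_acceptor_ok=True)
    return SpliceClass("generic_indel")


def _donor_ok_at(model: TranscriptModel, new_exon_end_plus1: int) -> bool | None:
    # advisory only: a novel 5' splice site inside an exon cannot be motif-checked
    # without genomic context beyond the stored flanks
    return None


# ---------------------------------------------------------------------------
# variant cDNA reconstruction
# ---------------------------------------------------------------------------

def snp_variant_cdna(model: TranscriptModel, pos: int, alt: str) -> str:
    seq = model.cdna_seq
    return seq[: pos - 1] + alt.upper() + seq[pos:]


def indel_variant_cdna(model: TranscriptModel, call: IndelCall) -> str:
    seq = model.cdna_seq
    if call.kind == "deletion":
        return seq[: call.start - 1] + seq[call.end :]
    return seq[: call.start] + call.seq + seq[call.start :]


def _translate_to_stop(cdna: str, cds_offset: int) -> tuple[str, bool]:
    """Translate from the start codon to the first stop; returns (residues, stop_found)."""
    cds = cdna[cds_offset - 1 :]
    cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate())
    stop = prot.find("*")
    if stop < 0:
        return prot, False
    return prot[:stop], True


# ---------------------------------------------------------------------------
# protein consequences
# ---------------------------------------------------------------------------

def annotate_snp(call: SnpCall, model: TranscriptModel) -> ProteinConsequence:
    """Silent or missense consequence of a coding single-base substitution."""
    pos, alt = call.cdna_position, call.alt_base.upper()
    if not model.cds_offset <= pos <= model.cds_end:
        raise CoordinateError(f"SNP position {pos} outside CDS")
    if alt == call.ref_base.upper():
        raise ValueError("alt equals ref")
    addr = model.cdna_to_codon(pos)
    if addr.codon_number > model.wt_protein_length:
        raise UnsupportedVariantError("substitution in the stop codon is out of modelled space")
    codon = list(model.codon_seq(addr.codon_number))
    codon[addr.offset - 1] = alt
    new_aa = str(Seq("".join(codon)).translate())
    wt_aa = model.wt_residue(addr.codon_number)
    if new_aa == "*":
        raise UnsupportedVariantError("substitution creates a premature stop (nonsense), out of modelled space")
    if new_aa == wt_aa:
        return ProteinConsequence("silent", "-", model.wt_protein_length)
    return ProteinConsequence("missense", f"p.{wt_aa}{addr.codon_number}{new_aa}",
                              model.wt_protein_length)


def annotate_indel(call: IndelCall, model: TranscriptModel) -> ProteinConsequence:
    """In-frame bookkeeping or frameshift translate-to-stop for a cDNA indel."""
    if call.kind == "deletion":
        if call.end >= model.cds_end - 2:  # reaches into the stop codon or beyond
            raise UnsupportedVariantError("event spans the CDS end")
        net = -(call.end - call.start + 1)
    else:
        if not model.cds_offset <= call.start < model.cds_end - 2:
            raise UnsupportedVariantError("insertion outside the coding body")
        net = len(call.seq)
    variant = indel_variant_cdna(model, call)
    protein, stop_found = _translate_to_stop(variant, model.cds_offset)

    if net % 3 != 0:
        wt = model.protein
        r = next((i + 1 for i, (a, b) in enumerate(zip(wt, protein)) if a != b),
                 min(len(wt), len(protein)) + 1)
        new_aa = protein[r - 1] if r <= len(protein) else "*"
        wt_aa = wt[r - 1] if r <= len(wt) else "?"
        notes = "" if stop_found else "no-stop, runs off transcript"
        return ProteinConsequence("frameshift_oof", f"p.{wt_aa}{r}{new_aa}-OOF",
                                  len(protein), notes=notes)

    k = abs(net) // 3
    expected = model.wt_protein_length + net // 3
    notes = "" if len(protein) == expected else (
        f"premature stop: translated length {len(protein)} != expected {expected}"
    )
    if call.kind == "insertion":
        addr = model.cdna_to_codon(call.start)
        res = model.wt_residue(addr.codon_number)
        name = f"p.{res}{addr.codon_number}Ins{k}"
        return ProteinConsequence("inframe_insertion", name, len(protein), notes=notes)

    first_addr = model.cdna_to_codon(call.start)
    last_addr = model.cdna_to_codon(call.end)
    if first_addr.offset == 1 and last_addr.offset == 3:
        first, last = first_addr.codon_number, last_addr.codon_number
    else:
        # hybrid junction codon: assign it to the downstream residue when it
        # still encodes it, otherwise to the upstream residue
        first_c = first_addr.codon_number
        hybrid = _hybrid_codon(model, call, first_c)
        hybrid_aa = str(Seq(hybrid).translate())
        if first_c + k <= model.wt_protein_length and hybrid_aa == model.wt_residue(first_c + k):
            first, last = first_c, first_c + k - 1
        elif hybrid_aa == model.wt_residue(first_c):
            first, last = first_c + 1, first_c + k
        else:
            first, last = first_c, first_c + k - 1
            notes = (notes + "; " if notes else "") + (
                f"hybrid junction codon encodes {hybrid_aa}, "
                f"differing from both flanking residues"
            )
    name = f"p.Δ{first}{EN_DASH}{last}"
    return ProteinConsequence("inframe_deletion", name, len(protein), notes=notes)


def _hybrid_codon(model: TranscriptModel, call: IndelCall, codon_number: int) -> str:
    """Sequence of the codon containing the deletion start, after deletion."""
    span_start, _ = model.codon_span(codon_number)
    variant = indel_variant_cdna(model, call)
    i = span_start - 1
    return variant[i : i + 3]


def count_out_of_frame(consequences: list[ProteinConsequence]) -> int:
    """Number of frameshift (out-of-frame) consequences."""
    return sum(1 for c in consequences if c.kind == "frameshift_oof")
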