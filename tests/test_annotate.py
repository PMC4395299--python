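"""Splice classification and protein-consequence annotation."""

import numpy as np
import pytest

from deepamp.annotate import (
    UnsupportedVariantError,
    annotate_indel,
    annotate_snp,
    classify_splice_event,
    count_out_of_frame,
    indel_variant_cdna,
)
from deepamp.calling import IndelCall, IndelCandidate, SnpCall
from deepamp.transcript import CoordinateError

from _oracles import apply_indel, translate_to_stop


def dele(s, e):
    return IndelCall(IndelCandidate("deletion", s, e), frozenset({"x"}))


def ins(anchor, seq):
    return IndelCall(IndelCandidate("insertion", anchor, anchor, seq), frozenset({"x"}))


def snp(pos, ref, alt):
    return SnpCall(pos, ref, alt, 0.01, 0.01, 0.01, 10)


# -- splice classification --------------------------------------------------

def test_whole_exon_deletion_is_skipping(kd_model):
    sp = classify_splice_event(dele(696, 825), kd_model)
    assert sp.category == "exon_skipping"
    assert sp.exons_involved == ("23",)


def test_multi_exon_deletion_is_skipping(kd_model):
    sp = classify_splice_event(dele(696, 923), kd_model)
    assert sp.category == "exon_skipping"
    assert sp.exons_involved == ("23", "24")


def test_exon_suffix_deletion_is_alt5ss(kd_model):
    sp = classify_splice_event(dele(733, 825), kd_model)
    assert sp.category == "partial_exon_deletion_alt5ss"
    assert sp.exons_involved == ("23",)


def test_exon_prefix_deletion_is_alt3ss(kd_model):
    sp = classify_splice_event(dele(826, 894), kd_model)
    assert sp.category == "partial_exon_deletion_alt3ss"
    assert sp.exons_involved == ("24",)


def test_junction_insertion_from_intron_3prime_end_is_retention(kd_model):
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    sp = classify_splice_event(ins(923, flank[-24:]), kd_model)
    assert sp.category == "intron_retention_alt3ss"
    assert sp.exons_involved == ("24",)
    assert "intron 24 partial retention" in sp.describe()


def test_junction_insertion_from_intron_5prime_start_is_retention(kd_model):
    flank = kd_model.exon_by_id("24").downstream_intron_seq
    sp = classify_splice_event(ins(923, flank[:18]), kd_model)
    assert sp.category == "intron_retention_alt5ss"


def test_interior_deletion_is_generic(kd_model):
    assert classify_splice_event(dele(740, 746), kd_model).category == "generic_indel"


def test_interior_insertion_is_generic(kd_model):
    assert classify_splice_event(ins(750, "ACGTACGT"), kd_model).category == "generic_indel"


def test_out_of_bounds_indel_rejected(kd_model):
    with pytest.raises(CoordinateError):
        classify_splice_event(dele(2000, 3000), kd_model)


# -- SNP consequences -------------------------------------------------------

def test_missense_substitutions(kd_model):
    c = annotate_snp(snp(872, "G", "A"), kd_model)
    assert (c.kind, c.name, c.protein_length) == ("missense", "p.R291Q", 680)
    c = annotate_snp(snp(1004, "G", "A"), kd_model)
    assert (c.kind, c.name) == ("missense", "p.R335Q")


@pytest.mark.parametrize("pos,ref,alt", [(747, "C", "T"), (825, "G", "A"),
                                         (894, "G", "A"), (909, "C", "T"), (975, "G", "A")])
def test_silent_third_position_substitutions(kd_model, pos, ref, alt):
    c = annotate_snp(snp(pos, ref, alt), kd_model)
    assert (c.kind, c.name, c.protein_length) == ("silent", "-", 680)


def test_alt_equal_ref_rejected(kd_model):
    with pytest.raises(ValueError):
        annotate_snp(snp(872, "G", "G"), kd_model)


def test_stop_codon_substitution_unsupported(kd_model):
    pos = kd_model.cds_end  # inside the stop codon
    with pytest.raises(UnsupportedVariantError):
        annotate_snp(snp(pos, kd_model.cdna_seq[pos - 1], "C"), kd_model)


# -- indel consequences -----------------------------------------------------

@pytest.mark.parametrize(
    "call_args,name,length",
    [
        ((696, 923), "p.Δ232–307", 604),
        ((733, 825), "p.Δ245–275", 649),
        ((826, 894), "p.Δ276–298", 657),
    ],
)
def test_inframe_deletions_printed_coordinates(kd_model, call_args, name, length):
    c = annotate_indel(dele(*call_args), kd_model)
    assert c.kind == "inframe_deletion"
    assert c.name == name
    assert c.protein_length == length


@pytest.mark.parametrize("k,name,length", [(24, "p.R308Ins8", 688), (36, "p.R308Ins12", 692)])
def test_inframe_intron_retention_insertions(kd_model, k, name, length):
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    c = annotate_indel(ins(923, flank[-k:]), kd_model)
    assert (c.kind, c.name, c.protein_length) == ("inframe_insertion", name, length)


def test_frameshift_names_and_lengths(kd_model):
    c = annotate_indel(dele(923, 924), kd_model)
    assert (c.kind, c.name) == ("frameshift_oof", "p.D309H-OOF")
    c = annotate_indel(dele(826, 923), kd_model)
    assert (c.kind, c.name) == ("frameshift_oof", "p.P276R-OOF")
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    c = annotate_indel(ins(923, flank[-106:]), kd_model)
    assert (c.kind, c.name) == ("frameshift_oof", "p.D309H-OOF")


def test_cds_end_spanning_event_unsupported(kd_model):
    with pytest.raises(UnsupportedVariantError):
        annotate_indel(dele(2040, 2043), kd_model)


def _random_event(rng, model):
    if rng.random() < 0.5:
        s = int(rng.integers(600, 1500))
        e = s + int(rng.integers(1, 250))
        return dele(s, e)
    anchor = int(rng.integers(600, 1500))
    seq = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 120))))
    return ins(anchor, seq)


def test_frameshift_lengths_match_translate_oracle(kd_model):
    """100 random fixture indels: frameshift truncation agrees with a
    brute-force translate-from-ATG oracle, in-frame events keep exact
    residue bookkeeping, and the frame dichotomy holds."""
    rng = np.random.default_rng(99)
    n_checked = 0
    while n_checked < 100:
        call = _random_event(rng, kd_model)
        net = len(call.seq) if call.kind == "insertion" else -(call.end - call.start + 1)
        try:
            cons = annotate_indel(call, kd_model)
        except UnsupportedVariantError:
            continue
        variant = apply_indel(kd_model.cdna_seq, call.kind, call.start, call.end, call.seq)
        assert variant == indel_variant_cdna(kd_model, call)
        oracle_protein = translate_to_stop(variant)
        if net % 3 != 0:
            assert cons.kind == "frameshift_oof"
            assert cons.protein_length == len(oracle_protein)
        else:
            assert cons.kind in ("inframe_deletion", "inframe_insertion")
            assert cons.protein_length == len(oracle_protein)
            if not cons.notes:  # no premature stop introduced
                assert cons.protein_length == kd_model.wt_protein_length + net // 3
        n_checked += 1


def test_oof_tally_of_printed_splice_variants(kd_model):
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    events = [dele(923, 924), dele(696, 825), dele(696, 923), dele(826, 923),
              dele(733, 825), dele(826, 894),
              ins(923, flank[-24:]), ins(923, flank[-36:]), ins(923, flank[-106:])]
    cons = [annotate_indel(ev, kd_model) for ev in events]
    assert count_out_of_frame(cons) == 4
    assert count_out_of_frame([]) == 0
    assert count_out_of_frame([c for c in cons if c.kind != "frameshift_oof"]) == 0
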