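"""SNP strand-bidirectional rule, dual INDEL detectors, normalization, consensus."""

import numpy as np
import pytest

from deepamp.calling import (
    IndelCall,
    IndelCandidate,
    build_indel_consensus,
    call_snps,
    cross_validate,
    detect_indels_gapped,
    detect_indels_splitread,
    equivalent_placements,
    merge_candidates,
    normalize_indel,
)
from deepamp.read_processing import Pileup, Read, align_reads, orient_reads, build_pileup
from deepamp.simulate import (
    SimulationConfig,
    VariantSpec,
    generate_reference,
    simulate_sample,
)

from conftest import variant_read


def _pileup_with_alt(ref, pos, alt, n_fwd_alt, n_rev_alt, depth_fwd, depth_rev):
    pile = Pileup(len(ref), ref_offset=1)
    ref_base = ref[pos - 1]
    for strand, depth, n_alt in (("+", depth_fwd, n_fwd_alt), ("-", depth_rev, n_rev_alt)):
        for p in range(1, len(ref) + 1):
            base = ref[p - 1]
            for i in range(depth):
                if p == pos and i < n_alt:
                    pile.add_base(p, alt, strand)
                else:
                    pile.add_base(p, base, strand)
    return pile


# -- SNP rule ---------------------------------------------------------------

def test_snp_accepted_when_both_strands_reach_threshold(kd_reference):
    # 0.6% on each strand at depth 1000/strand
    pile = _pileup_with_alt(kd_reference[:50], 20, "A" if kd_reference[19] != "A" else "C",
                            6, 6, 1000, 1000)
    calls = call_snps(pile, kd_reference[:50])
    assert len(calls) == 1
    assert calls[0].cdna_position == 20
    assert calls[0].freq_forward == pytest.approx(0.006)
    assert calls[0].freq_reverse == pytest.approx(0.006)


def test_snp_rejected_on_strand_imbalance(kd_reference):
    # 0.6% forward but 0.3% reverse: fails the bidirectional rule
    alt = "A" if kd_reference[19] != "A" else "C"
    pile = _pileup_with_alt(kd_reference[:50], 20, alt, 6, 3, 1000, 1000)
    assert call_snps(pile, kd_reference[:50]) == []


def test_snp_threshold_is_inclusive(kd_reference):
    # exactly 0.5% on both strands is accepted ("at least 0.5%")
    alt = "A" if kd_reference[19] != "A" else "C"
    pile = _pileup_with_alt(kd_reference[:50], 20, alt, 5, 5, 1000, 1000)
    assert len(call_snps(pile, kd_reference[:50])) == 1


def test_zero_depth_positions_skipped_and_logged(kd_reference):
    pile = Pileup(10, ref_offset=1)
    for p in range(1, 11):
        pile.add_base(p, kd_reference[p - 1], "+")  # forward only
    log = []
    assert call_snps(pile, kd_reference[:10], log=log) == []
    assert log  # skipped positions are reported


def test_threshold_monotonicity(kd_reference):
    rng = np.random.default_rng(5)
    ref = kd_reference[:80]
    pile = Pileup(len(ref), ref_offset=1)
    for strand in "+-":
        for p in range(1, len(ref) + 1):
            for _ in range(500):
                base = ref[p - 1] if rng.random() > 0.02 else rng.choice(list("ACGT"))
                pile.add_base(p, str(base), strand)
    prev = None
    for thr in (0.001, 0.005, 0.01, 0.05, 0.2):
        got = {(c.cdna_position, c.alt_base) for c in call_snps(pile, ref, threshold=thr)}
        if prev is not None:
            assert got <= prev
        prev = got


# -- detectors --------------------------------------------------------------

EVENTS = [
    ("deletion", 696, 825, ""),     # whole exon-23 analog, 130 nt
    ("deletion", 826, 923, ""),     # whole exon-24 analog, 98 nt
    ("deletion", 733, 825, ""),     # alt 5'ss partial deletion, 93 nt
]


@pytest.mark.parametrize("kind,a,b,_", EVENTS)
def test_detectors_agree_on_splice_deletions(kd_model, kd_amplicon, kind, a, b, _):
    read_seq = variant_read(kd_model, kd_amplicon, "deletion", a, b)
    a0, _a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : kd_amplicon[1]]
    reads = [Read("v", read_seq, strand="+")]
    alns = align_reads(reads, ref)
    gapped = [normalize_indel(c, kd_model)
              for c in detect_indels_gapped(alns, ref_offset=a0)]
    split = [normalize_indel(c, kd_model)
             for c in detect_indels_splitread(reads, ref, ref_offset=a0)]
    assert len(gapped) == len(split) == 1
    assert gapped[0].key == split[0].key == ("deletion", a, b, "")


@pytest.mark.parametrize("length", [24, 36, 106])
def test_detectors_agree_on_intron_retention_insertions(kd_model, kd_amplicon, length):
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    seq = flank[-length:]
    read_seq = variant_read(kd_model, kd_amplicon, "insertion", 923, seq)
    a0, a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : a1]
    reads = [Read("v", read_seq, strand="+")]
    gapped = [normalize_indel(c, kd_model)
              for c in detect_indels_gapped(align_reads(reads, ref), ref_offset=a0)]
    split = [normalize_indel(c, kd_model)
             for c in detect_indels_splitread(reads, ref, ref_offset=a0)]
    assert len(gapped) == len(split) == 1
    assert gapped[0].key == split[0].key
    assert gapped[0].kind == "insertion" and len(gapped[0].seq) == length


def test_wt_reads_yield_no_candidates(kd_model, kd_amplicon, kd_reference):
    reads = [Read("wt", kd_reference, strand="+")]
    assert detect_indels_gapped(align_reads(reads, kd_reference)) == []
    assert detect_indels_splitread(reads, kd_reference) == []


# -- normalization ----------------------------------------------------------

def test_equivalent_placements_preserve_variant_sequence(kd_model):
    # every enumerated placement must reproduce the same variant haplotype
    cand = IndelCandidate("deletion", 923, 924)
    ref = kd_model.cdna_seq
    variants = set()
    for p in equivalent_placements(cand, ref):
        variants.add(ref[: p.start - 1] + ref[p.end :])
    assert len(variants) == 1


def test_normalization_prefers_exon_boundary(kd_model):
    # c.923-924del shifts to c.924-925del, whose start is the exon-25 start
    norm = normalize_indel(IndelCandidate("deletion", 923, 924), kd_model)
    assert (norm.start, norm.end) == (924, 925)
    assert norm.start in kd_model.exon_starts


def test_normalization_left_aligns_in_repeats():
    model = generate_reference(3, [120, 120])
    seq = model.cdna_seq
    # find a dinucleotide repeat-free position: deletion in unique context stays put
    for s in range(30, 60):
        cand = IndelCandidate("deletion", s, s + 3)
        placements = equivalent_placements(cand, seq)
        norm = normalize_indel(cand, model)
        assert norm.key == placements[0].key  # leftmost (no boundary involved)
        assert norm.start <= s


def test_insertion_normalization_shifts_through_context(kd_model):
    # inserting a copy of the base after the anchor is equivalent to
    # inserting at the next anchor; normalized placement is deterministic
    ref = kd_model.cdna_seq
    base = ref[930]
    a = normalize_indel(IndelCandidate("insertion", 930, 930, base), kd_model)
    b = normalize_indel(IndelCandidate("insertion", 931, 931, base), kd_model)
    assert a.key == b.key


# -- cross-validation -------------------------------------------------------

def test_cross_validation_requires_both_detectors():
    g = [IndelCandidate("deletion", 10, 12, "", frozenset({"r1"}), "gapped"),
         IndelCandidate("deletion", 50, 52, "", frozenset({"r2"}), "gapped")]
    s = [IndelCandidate("deletion", 10, 12, "", frozenset({"r1", "r3"}), "splitread")]
    calls = cross_validate(g, s)
    assert len(calls) == 1
    assert calls[0].start == 10
    assert calls[0].read_ids == {"r1", "r3"}


def test_single_read_support_suffices(kd_model, kd_amplicon):
    # no frequency floor: 1 supporting read out of 200 validates
    cfg = SimulationConfig(depth_mean=200, depth_sd=0, amplicons=[kd_amplicon])
    specs = [VariantSpec.deletion(696, 825, 0.005)]
    a0, a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : a1]
    for seed in range(30):
        rs, truth = simulate_sample(kd_model, specs, cfg, rng=seed)
        row = truth.realized("c.696-825del")
        if row["n_fwd"] + row["n_rev"] == 1:
            break
    else:
        pytest.fail("no seed realized exactly one supporting read")
    oriented, _ = orient_reads(rs.reads, ref)
    alns = align_reads(oriented, ref)
    gapped = merge_candidates([normalize_indel(c, kd_model)
                               for c in detect_indels_gapped(alns, ref_offset=a0)])
    split = merge_candidates([normalize_indel(c, kd_model)
                              for c in detect_indels_splitread(oriented, ref, ref_offset=a0)])
    calls = cross_validate(gapped, split)
    assert [c.candidate.key for c in calls] == [("deletion", 696, 825, "")]
    assert len(calls[0].read_ids) == 1


# -- consensus --------------------------------------------------------------

def test_consensus_matches_variant_haplotype(kd_model, kd_amplicon):
    a0, a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : a1]
    read_seq = variant_read(kd_model, kd_amplicon, "deletion", 696, 825)
    reads = {f"r{i}": Read(f"r{i}", read_seq, strand="+") for i in range(10)}
    call = IndelCall(IndelCandidate("deletion", 696, 825), frozenset(reads))
    cons = build_indel_consensus(call, reads, ref, ref_offset=a0, flank=25)
    expected = kd_model.cdna_seq[696 - 26 : 695] + kd_model.cdna_seq[825 : 825 + 25]
    assert cons == expected


def test_consensus_majority_overrides_single_error(kd_model, kd_amplicon):
    a0, a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : a1]
    read_seq = variant_read(kd_model, kd_amplicon, "deletion", 696, 825)
    reads = {f"r{i}": Read(f"r{i}", read_seq, strand="+") for i in range(9)}
    # one read with a substitution error in the downstream flank
    j = 696 - a0 + 5
    errseq = read_seq[:j] + ("A" if read_seq[j] != "A" else "C") + read_seq[j + 1 :]
    reads["bad"] = Read("bad", errseq, strand="+")
    call = IndelCall(IndelCandidate("deletion", 696, 825), frozenset(reads))
    cons = build_indel_consensus(call, reads, ref, ref_offset=a0, flank=25)
    expected = kd_model.cdna_seq[696 - 26 : 695] + kd_model.cdna_seq[825 : 825 + 25]
    assert cons == expected


def test_consensus_requires_support(kd_reference):
    call = IndelCall(IndelCandidate("deletion", 700, 710), frozenset())
    with pytest.raises(ValueError):
        build_indel_consensus(call, {}, kd_reference)


def test_intron_retention_consensus_contains_injected_flank(kd_model, kd_amplicon):
    a0, a1 = kd_amplicon
    ref = kd_model.cdna_seq[a0 - 1 : a1]
    flank = kd_model.exon_by_id("25").upstream_intron_seq
    read_seq = variant_read(kd_model, kd_amplicon, "insertion", 923, flank[-24:])
    reads = {f"r{i}": Read(f"r{i}", read_seq, strand="+") for i in range(5)}
    call = IndelCall(IndelCandidate("insertion", 923, 923, flank[-24:]), frozenset(reads))
    cons = build_indel_consensus(call, reads, ref, ref_offset=a0, flank=20)
    assert flank[-24:] in cons
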