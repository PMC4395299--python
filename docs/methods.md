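# Methods

This note documents the models, rules and numerical choices behind
`deepamp`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real sequencing data.

## Transcript model and coordinates

The reference is the mature fusion-transcript cDNA, numbered HGVS-style
with `c.1` = the first base of the start codon (`cds_offset = 1`), so codon
*n* spans `c.3n−2..3n`. This frame is the only one consistent with the
known missense coordinates of the system (a middle-position G>A at c.872 in
an Arg codon at residue 291, and at c.1004 in residue 335). The published
numbering of the underlying GenBank record may include a 5' UTR; we fix
`c.1 = ATG` and flag rather than assume agreement with the record's own
numbering.

Exon/intron structure is stored as per-exon intron *flanks* (first/last
~150 nt of each intron) rather than a genomic contig — sufficient for
splice classification, which only ever asks whether an inserted sequence
is a terminal segment of an adjacent intron, and keeps fixtures small.
Non-empty flanks must carry canonical GT (donor) / AG (acceptor)
dinucleotides; the model validates exon contiguity, CDS frame, translated
length and absence of internal stops eagerly at construction. The fusion
transcript is modelled as a single CDS; the 5' fusion-partner portion is
not distinguished structurally, because only the amplified kinase-domain
region matters here. Fusion residue *n* maps to full-length receptor
residue *n* + 940 (a fixed shift; R335 ↔ R1275, R291 ↔ R1231).

## The kinase-domain fixture

`alk_like_model()` generates a 2043-nt cDNA (680-aa protein) with exon
lengths 695/130/98/1120, i.e. the exon-23 analog spans c.696–825, exon 24
c.826–923, exon 25 starts at c.924 — the geometry implied by the reported
exon-skipping coordinates. Background codons are drawn uniformly from the
61 sense codons; a small set of codons is pinned so the fixture carries the
reported residue identities (S232, F234, P276, R291, R308, D309, R335,
Y664; four-fold-degenerate third positions at the five silent-SNP sites)
and so that the junction-spanning frameshifts reproduce the reported
protein-change names: after the exon-24 skip the hybrid codon at residue
276 reads Arg (p.P276R-OOF), and after the 2-nt junction deletion residue
308 is preserved while 309 becomes His (p.D309H-OOF). One reported name is
*not* reproducible on any sequence: with WT residue 232 = Ser and WT 276 =
Pro (codon 276 = c.826–828 = CCN), the post-exon-23-skip hybrid codon
c.694,695,826 necessarily re-encodes Ser, so the exon-23-skip frameshift
diverges at residue 233 on this fixture (the published S232R would require
a different codon 276). Frameshift truncation lengths depend on the
downstream base sequence and are therefore fixture-specific; they are
checked against a brute-force translate-to-stop oracle, not against
published values. The in-frame consequences (604, 649, 657, 688, 692
residues) are pure coordinate arithmetic and are reproduced exactly.

The intron-24 3' flank is additionally constrained so that its terminal
24- and 36-nt segments, spliced in at the exon-24/25 junction, introduce no
stop codon (these are the in-frame partial-retention events), and so the
106-nt retention places a His codon at residue 309.

## Read simulation

Study conditions are the generator defaults: per-amplicon depth ~
round(Normal(2234, 734)) truncated at ≥ 1; strand chosen per read at
fraction 0.5 forward; reverse reads emitted reverse-complemented; 10-nt
MID barcodes (pairwise Hamming distance ≥ 3) prefixed after error
application. Variants are whole haplotypes mixed multinomially at their
target frequencies; the realized per-strand counts are recorded in a truth
table. The error model is deliberately simple: uniform substitutions at a
configurable per-base rate plus 1-nt insertions/deletions at homopolymer
runs ≥ 3 — the dominant artifact mode of pyrosequencing chemistry.
Flowgram simulation, PCR chimeras and quality-score realism are out of
scope. Per-amplicon depth is split evenly when several amplicons are
configured (the real per-amplicon pooling ratio is not reported; equimolar
is assumed). The default amplicon on the fixture is c.550–1100, chosen so
every variant of interest lies inside one amplicon with ≥ 145-nt flanks
(551–657-nt reads, within pyrosequencing read-length range).

Consequence: passing tests show the *rules* behave as specified under
binomial sampling and homopolymer noise. They do not establish performance
under flowgram-specific error correlation, chimeric reads, primer-site
artifacts or unbalanced amplicon pooling.

## Alignment

Semi-global ("fit") affine-gap alignment of the full read against a
substring of the amplicon reference: Gotoh three states, free end gaps on
the reference side only, vectorised row-by-row with the within-row
reference-gap state resolved in closed form by a running prefix maximum.
Gap cost convention: a gap of length L costs `open + (L−1)·extend`.
Traceback is deterministic — tie order diagonal > up (read insertion) >
left (reference deletion), alignment end at the leftmost best-scoring
reference column. Scores are verified against an independent plain-loop
dynamic-programming oracle on hundreds of random instances.

Scoring defaults are match +2, mismatch −3, gap open −10, gap extend −1.
The gap geometry was chosen against two constraints pulling in opposite
directions: (i) a 1-nt homopolymer indel must be expensive enough (−10)
not to absorb a genuine 0.5%-frequency substitution into a gap column, and
(ii) a splice-sized deletion (98–228 nt) must be *cheaper* than
garbage-aligning the shorter amplicon flank with micro-gaps, which costs
roughly 2.5–3 points per flanking base. With ~150-nt flanks this holds for
deletions up to ~350 nt; a steeper extension penalty (e.g. −2) fails
already at 130 nt, fragmenting exon-skip alignments and breaking
dual-detector validation. Batch alignment caches the dynamic programme per
unique read sequence, which collapses the cost on deep amplicon data where
most reads are identical.

Read orientation uses shared k-mer counts (k = 11) of the read vs. its
reverse complement against the reference, with ties resolved forward and a
floor of 4 shared k-mers below which a read is flagged unalignable. A
score- or edit-distance-based orientation was rejected: a read spanning a
228-nt deletion is further (in edit distance) from the contiguous
reference than a random-level reverse-strand hit, whereas k-mer support is
unaffected by large collinear events. Random 300-mers share ~0.04 11-mers
with the reference in expectation, so the floor of 4 separates null reads
cleanly (verified on simulated nulls).

## Variant calling

**SNPs.** Per position and strand, denominators are base calls only
(deletion observations are excluded); a call requires the alt fraction to
reach the threshold on both strands, with "at least 0.5%" implemented
inclusively (an accepted variant is reported at exactly 0.5% in the
source system). Positions with zero base-call depth on either strand are
skipped and logged. Raising the threshold can only shrink the call set
(tested as a monotonicity property).

**INDEL detectors.** The gapped detector turns every alignment gap run
into a candidate. The split-read detector indexes reference 11-mers
(dropping k-mers with > 4 reference hits), collects maximal co-diagonal
exact-match runs per read, keeps blocks ≥ 20 nt, and chains the longest
block with the best order-consistent partner on another diagonal;
junction micro-homology (block overlap in read or reference) is trimmed
off the downstream block. Two blocks adjacent in the read but split on
the reference give a deletion; adjacent on the reference but split in the
read give an insertion carrying the unaligned read sequence. The 20-nt
block floor suppresses spurious chains from homopolymer noise at
ultra-deep coverage; it also sets the detector's blind spot (events within
20 nt of a read end).

**Normalization and cross-validation.** All sequence-equivalent placements
of an event (shifting through repeated context) are enumerated; the
canonical placement is the one whose breakpoints coincide with an exon
boundary if any does (deletions: start at an exon start or end at an exon
end; insertions: anchored at an exon end), otherwise the leftmost, ties
leftmost. This mirrors how splice-consistent coordinates are reported: the
junction-spanning 2-nt deletion c.923-924del canonicalizes to
c.924-925del, i.e. loss of the first two bases of exon 25, with an
identical protein consequence. Cross-validation intersects the two
detectors' normalized candidate sets exactly (kind, coordinates, inserted
sequence); support is pooled as the union of supporting reads, and no
frequency floor is applied — single-read events are honored, so with the
error model on, the raw dual-validated set is large and dominated by
homopolymer artifacts, exactly the situation that motivates downstream
classification and review. Consensus sequences are per-column majorities
of the supporting reads over the event ± 25 nt, located in each read by
infix alignment, ties resolved to the variant-template base.

## Splice classification and protein consequences

Classification is rule-based on normalized events: complete consecutive
exons → skipping; strict suffix of one exon → alternative 5' splice site;
strict prefix → alternative 3'; junction insertion matching a terminal
segment of the stored intron flank → partial intron retention (3'-end
segment → alternative 3' site, 5'-start → alternative 5'); everything else
is a generic indel. GT/AG checking at novel junctions is advisory only —
categories are assigned by alignment geometry, not motif, and the stored
flanks cannot motif-check a site deep inside an exon.

In-frame deletions not aligned to codon boundaries are named by the
removed-codon range implied by the hybrid junction codon: if the hybrid
codon still encodes the downstream residue, the deletion is reported from
the first changed codon (e.g. the 228-nt junction deletion gives p.Δ232–307
because the hybrid codon re-encodes residue 308's Arg); if it encodes the
upstream residue the range shifts by one; if it encodes neither, the
downstream assignment is used and the substitution is noted. One reported
naming is knowingly not reproduced: the 69-nt deletion c.826-894 spans 23
codons and is printed here as p.Δ276–298 (657 residues), whereas the
source table prints a 24-residue range with the same 657-residue length —
the length, which is the checkable quantity, is reproduced and the naming
discrepancy flagged. In-frame protein lengths are computed by translating
the reconstructed variant CDS and verified to equal `680 ± net/3`;
a premature stop introduced by an inserted sequence would be detected and
noted. Frameshifts are named from the first divergent residue and
truncated at the first stop of the shifted frame; if no stop occurs before
the end of the modelled transcript the consequence is flagged "no-stop"
rather than guessed. Substitutions in the stop codon and events spanning
the CDS end are outside the modelled space and raise a typed error, which
the pipeline logs and skips.

## Pipeline, determinism, reporting

Samples are processed independently (demultiplex → orient → align →
pileup → call → cross-validate → consensus → classify → annotate) and
merged by variant label and description, mirroring per-patient detection
counts ("Patients" column) and frequency ranges. Indel frequencies are
supporting reads over covering reads at the event start, per amplicon. All
randomness flows from one seed through a single generator; reruns are
byte-identical, and every run writes a provenance JSON with all effective
parameters. Exports: FASTQ/FASTA (Biopython), SAM (pysam), per-sample VCF
with strand-frequency/ detector INFO fields (pysam), TSV tables (pandas).

## Problem sizes used in tests and the acceptance script

Unit and property tests run at depths 40–600 where the property is
depth-independent; the SNP-rule check runs at 2000 reads/strand and the
dual-detector recovery at depth 2234 with three events injected at 0.5%
each — the smallest scale at which the study-condition claims are
meaningful. Oracle sweeps use 200 random alignment instances (≤ 60 nt) and
100 random indels. The four-patient cohort driver runs at the full study
depth with the error model on.

## Known limitations

- The affine-gap detector's large-deletion reach is bounded by flank
  economics (~350 nt under the defaults); far larger events would be
  split-read-only and hence fail dual validation by design.
- Orientation and the split-read detector assume ≥ 4 and ≥ 20 nt of
  intact sequence respectively; heavily corrupted reads drop out rather
  than degrade gracefully.
- The simulator draws haplotypes independently per read; linkage between
  co-occurring variants on one molecule is not modelled, and each
  simulated haplotype carries exactly one variant.
- Frequencies are per-amplicon covering-read fractions; whether the
  source frequencies are per-amplicon or per-sample is unspecified there.
- The aligner is quality-blind; base qualities are carried but unused.
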