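#!/usr/bin/env python
"""Build and persist the kinase-domain transcript fixture.

Constructs the synthetic fusion-kinase transcript (2043-nt cDNA, 680-aa
protein, exon-23 analog at c.696-825, exon 24 at c.826-923, exon 25 from
c.924) and writes it under results/reference/. Prints the coordinate
checks that pin the reading frame: c.872 sits in codon 291 and c.1004 in
codon 335, both at the middle position, and the engineered residues
(S232, F234, P276, R291, R308, D309, R335, Y664) are in place.
"""

from pathlib import Path

from deepamp.simulate import KD_AMPLICON, alk_like_model
from deepamp.transcript import npmalk_to_alk_residue

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    model = alk_like_model()
    out = ROOT / "results" / "reference"
    path = model.save(out)
    print(f"wrote {path} (+ cdna.fasta)")
    print(f"cDNA length {len(model.cdna_seq)} nt, WT protein {model.wt_protein_length} aa")
    for ex in model.exons:
        print(f"  exon {ex.exon_id}: c.{ex.cdna_start}-{ex.cdna_end} ({ex.length} nt)")
    print(f"amplicon: c.{KD_AMPLICON[0]}-{KD_AMPLICON[1]}")
    for pos in (872, 1004):
        addr = model.cdna_to_codon(pos)
        print(f"c.{pos} -> codon {addr.codon_number}, offset {addr.offset} "
              f"(WT {model.wt_residue(addr.codon_number)})")
    for n in (234, 291, 335, 664):
        print(f"fusion residue {model.wt_residue(n)}{n} = receptor residue "
              f"{model.wt_residue(n)}{npmalk_to_alk_residue(n)}")


if __name__ == "__main__":
    main()
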