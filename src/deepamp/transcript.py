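"""Reference transcript model for a fusion-kinase cDNA.

The pipeline works in transcript (cDNA) space: the reference is the mature
fusion mRNA, numbered HGVS-style with c.1 = the first base of the start
codon. Exon/intron structure is carried as per-exon intron *flanks* (the
first/last bases of each intron), which is all the splice classifier needs
to recognise exon skipping, alternative splice sites and partial intron
retention without a genomic contig.

Residue numbering in the fusion protein maps onto the full-length receptor
kinase by a fixed offset of +940 (e.g. fusion residue 335 is receptor
residue 1275).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DONOR = "GT"
ACCEPTOR = "AG"
_STOPS = {"TAA", "TAG", "TGA"}

#: residue-number shift between the fusion kinase and the full-length receptor
ALK_RESIDUE_OFFSET = 940


class ModelError(ValueError):
    """Transcript model violates a structural or consistency invariant."""


class CoordinateError(ValueError):
    """A cDNA/codon coordinate is outside the modelled range."""


@dataclass(frozen=True)
class ExonRecord:
    """One exon in cDNA coordinates with its flanking intron sequence.

    ``upstream_intron_seq`` is the 3' end of the preceding intron (ends with
    the acceptor dinucleotide), ``downstream_intron_seq`` the 5' start of the
    following intron (starts with the donor dinucleotide). Either may be
    empty for terminal exons.
    """

    exon_id: str
    cdna_start: int
    cdna_end: int
    upstream_intron_seq: str = ""
    downstream_intron_seq: str = ""

    def __post_init__(self) -> None:
        if self.cdna_start > self.cdna_end:
            raise ModelError(
                f"exon {self.exon_id}: start {self.cdna_start} > end {self.cdna_end}"
            )

    @property
    def length(self) -> int:
        return self.cdna_end - self.cdna_start + 1


@dataclass(frozen=True)
class CodonAddress:
    """1-based codon number plus offset (1..3) within the codon."""

    codon_number: int
    offset: int

    def __post_init__(self) -> None:
        if self.codon_number < 1 or self.offset not in (1, 2, 3):
            raise CoordinateError(f"invalid codon address {self!r}")


class TranscriptModel:
    """Validated reference transcript: cDNA, exon structure, CDS frame.

    All invariants are checked eagerly at construction:

    * exons tile ``1..len(cdna_seq)`` contiguously without gaps/overlaps;
    * the CDS (from ``cds_offset``) translates to ``wt_protein_length``
      residues followed by a single stop, with no internal stop codon;
    * non-empty intron flanks carry canonical GT / AG dinucleotides.
    """

    def __init__(
        self,
        cdna_seq: str,
        exons: list[ExonRecord],
        wt_protein_length: int,
        cds_offset: int = 1,
        name: str = "transcript",
    ) -> None:
        cdna_seq = cdna_seq.upper()
        if not exons:
            raise ModelError("at least one exon required")
        if set(cdna_seq) - set("ACGTN"):
            raise ModelError("cDNA contains non-nucleotide characters")
        pos = 1
        for ex in exons:
            if ex.cdna_start != pos:
                raise ModelError(
                    f"exon {ex.exon_id} starts at {ex.cdna_start}, expected {pos}: "
                    "exons must tile the cDNA contiguously"
                )
            pos = ex.cdna_end + 1
        if pos - 1 != len(cdna_seq):
            raise ModelError(
                f"exons span 1..{pos - 1} but cDNA has length {len(cdna_seq)}"
            )
        for ex in exons[:-1]:
            if ex.downstream_intron_seq and not ex.downstream_intron_seq.upper().startswith(DONOR):
                raise ModelError(f"exon {ex.exon_id}: downstream intron lacks GT donor")
        for ex in exons[1:]:
            if ex.upstream_intron_seq and not ex.upstream_intron_seq.upper().endswith(ACCEPTOR):
                raise ModelError(f"exon {ex.exon_id}: upstream intron lacks AG acceptor")

        cds_end = cds_offset + 3 * (wt_protein_length + 1) - 1
        if cds_end > len(cdna_seq):
            raise ModelError(
                f"CDS end {cds_end} beyond cDNA length {len(cdna_seq)}"
            )
        cds = cdna_seq[cds_offset - 1 : cds_end]
        protein = str(Seq(cds).translate())
        if not protein.endswith("*") or "*" in protein[:-1]:
            raise ModelError("CDS must end with exactly one stop codon and contain no internal stop")
        if len(protein) - 1 != wt_protein_length:
            raise ModelError(
                f"translated length {len(protein) - 1} != declared wt_protein_length {wt_protein_length}"
            )

        self.cdna_seq = cdna_seq
        self.exons = list(exons)
        self.wt_protein_length = wt_protein_length
        self.cds_offset = cds_offset
        self.name = name
        self._protein = protein[:-1]

    # -- basic accessors ---------------------------------------------------

    @property
    def cds_end(self) -> int:
        """Last base of the stop codon, 1-based."""
        return self.cds_offset + 3 * (self.wt_protein_length + 1) - 1

    @property
    def protein(self) -> str:
        """WT protein sequence (no stop symbol)."""
        return self._protein

    def wt_residue(self, codon_number: int) -> str:
        if not 1 <= codon_number <= self.wt_protein_length:
            raise CoordinateError(f"codon {codon_number} outside protein 1..{self.wt_protein_length}")
        return self._protein[codon_number - 1]

    def exon_of(self, pos: int) -> ExonRecord:
        for ex in self.exons:
            if ex.cdna_start <= pos <= ex.cdna_end:
                return ex
        raise CoordinateError(f"cDNA position {pos} outside transcript")

    def exon_by_id(self, exon_id: str) -> ExonRecord:
        for ex in self.exons:
            if ex.exon_id == exon_id:
                return ex
        raise KeyError(exon_id)

    @property
    def exon_starts(self) -> set[int]:
        return {ex.cdna_start for ex in self.exons}

    @property
    def exon_ends(self) -> set[int]:
        return {ex.cdna_end for ex in self.exons}

    # -- coordinate arithmetic --------------------------------------------

    def cdna_to_codon(self, pos: int) -> CodonAddress:
        """Map a CDS cDNA position to (codon number, offset); codon n spans 3n-2..3n."""
        if not self.cds_offset <= pos <= self.cds_end:
            raise CoordinateError(
                f"position {pos} outside CDS {self.cds_offset}..{self.cds_end}"
            )
        rel = pos - self.cds_offset + 1
        codon = -(-rel // 3)  # ceil
        return CodonAddress(codon, rel - 3 * (codon - 1))

    def codon_span(self, codon_number: int) -> tuple[int, int]:
        """Closed cDNA interval of a codon (stop codon = wt_protein_length + 1)."""
        if not 1 <= codon_number <= self.wt_protein_length + 1:
            raise CoordinateError(f"codon {codon_number} out of range")
        start = self.cds_offset + 3 * (codon_number - 1)
        return (start, start + 2)

    def codon_seq(self, codon_number: int) -> str:
        s, e = self.codon_span(codon_number)
        return self.cdna_seq[s - 1 : e]

    # -- serialization -----------------------------------------------------

    def to_dict(self, fasta_path: str | None = None) -> dict:
        d = {
            "name": self.name,
            "wt_protein_length": self.wt_protein_length,
            "cds_offset": self.cds_offset,
            "exons": [
                {
                    "exon_id": ex.exon_id,
                    "cdna_start": ex.cdna_start,
                    "cdna_end": ex.cdna_end,
                    "upstream_intron_seq": ex.upstream_intron_seq,
                    "downstream_intron_seq": ex.downstream_intron_seq,
                }
                for ex in self.exons
            ],
        }
        if fasta_path is not None:
            d["cdna_fasta"] = fasta_path
        else:
            d["cdna_seq"] = self.cdna_seq
        return d

    def save(self, directory: str | Path) -> Path:
        """Write ``model.json`` plus ``cdna.fasta`` under *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta = directory / "cdna.fasta"
        SeqIO.write([SeqRecord(Seq(self.cdna_seq), id=self.name, description="")], fasta, "fasta")
        path = directory / "model.json"
        path.write_text(json.dumps(self.to_dict(fasta_path=fasta.name), indent=1))
        return path

    @classmethod
    def load(cls, json_path: str | Path) -> "TranscriptModel":
        json_path = Path(json_path)
        d = json.loads(json_path.read_text())
        if "cdna_seq" in d:
            seq = d["cdna_seq"]
        else:
            rec = next(SeqIO.parse(json_path.parent / d["cdna_fasta"], "fasta"))
            seq = str(rec.seq)
        exons = [ExonRecord(**e) for e in d["exons"]]
        return cls(
            seq,
            exons,
            wt_protein_length=d["wt_protein_length"],
            cds_offset=d.get("cds_offset", 1),
            name=d.get("name", "transcript"),
        )


def build_transcript_model(
    exon_records: list[ExonRecord],
    cdna_seq: str,
    wt_protein_length: int,
    cds_offset: int = 1,
    name: str = "transcript",
) -> TranscriptModel:
    """Validate and assemble a :class:`TranscriptModel` (all checks eager)."""
    return TranscriptModel(cdna_seq, exon_records, wt_protein_length, cds_offset, name)


def npmalk_to_alk_residue(n: int) -> int:
    """Fusion-kinase residue number -> full-length receptor residue (n + 940)."""
    if n < 1:
        raise CoordinateError("residue numbers are 1-based")
    return n + ALK_RESIDUE_OFFSET


def alk_to_npmalk_residue(n: int) -> int:
    """Inverse of :func:`npmalk_to_alk_residue`."""
    if n <= ALK_RESIDUE_OFFSET:
        raise CoordinateError(f"receptor residue {n} has no fusion counterpart")
    return n - ALK_RESIDUE_OFFSET
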