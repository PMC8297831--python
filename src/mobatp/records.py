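"""Core record types shared by all pipeline stages.

Coordinates are 1-based inclusive throughout (GFF3 convention); amino-acid
domain coordinates follow the same convention, matching HMMER output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: the 20 standard residues plus X for unknowns
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class GeneRecord:
    """A gene call on a contig: the unit of neighborhood analysis."""

    contig_id: str
    gene_id: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    strand: str  # "+" or "-"
    protein_seq: str = ""
    annotation: str = ""

    def validate(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.protein_seq:
            bad = set(self.protein_seq) - VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"gene {self.gene_id}: invalid residues {sorted(bad)}"
                )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class DomainHit:
    """One domain annotation on a protein (e.g., a Pfam match)."""

    protein_id: str
    accession: str
    name: str
    e_value: float
    ali_start: int  # aa, 1-based inclusive
    ali_end: int  # aa, 1-based inclusive

    def validate(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"{self.protein_id}: negative e-value {self.e_value}")
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"{self.protein_id}: bad alignment span "
                f"({self.ali_start}, {self.ali_end})"
            )


@dataclass
class HomologyHit:
    """One pairwise homology search hit (tabular BLAST row)."""

    query_id: str
    subject_id: str
    e_value: float
    bitscore: float


@dataclass
class ContigTaxonomy:
    """Per-contig tally of proteins whose best database hit is cellular."""

    contig_id: str
    n_proteins: int
    n_cellular_besthits: int  # best hits to bacteria or archaea

    def validate(self) -> None:
        if self.n_cellular_besthits > self.n_proteins:
            raise ValueError(
                f"contig {self.contig_id}: {self.n_cellular_besthits} cellular "
                f"best-hits exceed {self.n_proteins} proteins"
            )

    @property
    def cellular_fraction(self) -> float:
        if self.n_proteins == 0:
            return 0.0
        return self.n_cellular_besthits / self.n_proteins
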