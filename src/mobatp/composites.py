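"""Composite ATPase protein detection, filtering and categorization.

A composite ATPase protein carries at least one ATPase domain fused with at
least one other functional domain. Candidates from metagenomic contigs with
a majority of cellular (bacterial/archaeal) best hits are excluded as likely
non-mobilome, and duplicate gene calls (same coordinates or identical
sequence on a contig, an artifact of the gene caller) are collapsed to one
representative. Survivors are assigned a functional category from a keyword
map over their non-ATPase domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from mobatp.detect import DEFAULT_E_CUTOFF, DEFAULT_KEYWORDS, _keyword_match
from mobatp.records import ContigTaxonomy, DomainHit, GeneRecord

UNKNOWN_CATEGORY = "unknown/DUF"

#: keyword -> category, in priority order (first matching keyword wins)
DEFAULT_CATEGORY_MAP: list[tuple[str, str]] = [
    ("nuclease", "nuclease"),
    ("endonuclease", "nuclease"),
    ("PIN", "nuclease"),
    ("LAGLIDADG", "nuclease"),
    ("HNH", "nuclease"),
    ("ResIII", "nuclease"),
    ("protease", "protease"),
    ("peptidase", "protease"),
    ("Lon", "protease"),
    ("ClpP", "protease"),
    ("FtsH", "protease"),
    ("helicase", "helicase"),
    ("SNF2", "helicase"),
    ("DEAD", "helicase"),
    ("DEAH", "helicase"),
    ("polymerase", "polymerase"),
    ("primase", "polymerase"),
    ("DnaK", "chaperone"),
    ("HSP", "chaperone"),
    ("chaperone", "chaperone"),
    ("ClpB", "chaperone"),
    ("ABC", "transport/packaging"),
    ("terminase", "transport/packaging"),
    ("transport", "transport/packaging"),
    ("secretion", "transport/packaging"),
    ("FtsK", "transport/packaging"),
    ("portal", "transport/packaging"),
    ("virE", "virE"),
    ("virulence", "virE"),
    ("MutS", "DNA-repair"),
    ("RecA", "DNA-repair"),
    ("RAD", "DNA-repair"),
    ("CobQ", "nucleotide-binding"),
    ("CobB", "nucleotide-binding"),
    ("MinD", "nucleotide-binding"),
    ("ParA", "nucleotide-binding"),
]

CATEGORIES = [
    "nuclease",
    "protease",
    "helicase",
    "polymerase",
    "chaperone",
    "transport/packaging",
    "virE",
    "DNA-repair",
    "nucleotide-binding",
    UNKNOWN_CATEGORY,
]


@dataclass
class CompositeProtein:
    """A protein with >=1 ATPase domain fused to >=1 other functional domain."""

    protein_id: str
    contig_id: str
    atpase_hits: list[DomainHit]
    functional_hits: list[DomainHit]
    category: str = UNKNOWN_CATEGORY
    excluded_cellular: bool = False
    duplicate_of: Optional[str] = None

    @property
    def n_atpase_domains(self) -> int:
        return len(self.atpase_hits)


def detect_composites(
    genes: Sequence[GeneRecord],
    hits: Iterable[DomainHit],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> list[CompositeProtein]:
    """Find proteins with >=1 qualifying ATPase hit and >=1 other domain.

    Hits must pass the e-value cutoff; the ATPase/functional split follows
    the keyword rule (name or accession contains "ATP" or "AAA",
    case-insensitive). Output is ordered by protein_id.
    """
    by_gene = {g.gene_id: g for g in genes}
    grouped: dict[str, tuple[list[DomainHit], list[DomainHit]]] = {}
    for h in hits:
        if h.e_value > e_cutoff:
            continue
        atp, fun = grouped.setdefault(h.protein_id, ([], []))
        (atp if _keyword_match(h, keywords) else fun).append(h)
    out = []
    for pid in sorted(grouped):
        atp, fun = grouped[pid]
        if not atp or not fun:
            continue
        gene = by_gene.get(pid)
        out.append(
            CompositeProtein(
                protein_id=pid,
                contig_id=gene.contig_id if gene else "",
                atpase_hits=atp,
                functional_hits=fun,
            )
        )
    return out


def exclude_cellular_contigs(
    composites: Sequence[CompositeProtein],
    taxonomy: Sequence[ContigTaxonomy],
    threshold: float = 0.5,
) -> list[CompositeProtein]:
    """Flag composites on contigs with strictly >threshold cellular best hits.

    A contig at exactly the threshold (e.g., 50%) is retained. Returns the
    full collection with ``excluded_cellular`` set; survivors are the records
    with the flag False.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    by_contig = {t.contig_id: t for t in taxonomy}
    missing = sorted({c.contig_id for c in composites} - set(by_contig))
    if missing:
        raise ValueError(f"no taxonomy for contig(s): {missing[:5]}")
    for c in composites:
        c.excluded_cellular = by_contig[c.contig_id].cellular_fraction > threshold
    return list(composites)


def deduplicate(
    composites: Sequence[CompositeProtein],
    genes: Sequence[GeneRecord],
) -> list[CompositeProtein]:
    """Collapse duplicate gene calls among composite candidates.

    Two records are duplicates when their genes share (contig, start, end,
    strand) or have identical protein sequences on the same contig — the
    observable signature of redundant calls from the gene predictor. The
    lexicographically smallest gene_id of each group is kept; the others get
    ``duplicate_of`` set to it. Idempotent.
    """
    by_gene = {g.gene_id: g for g in genes}
    ids = [c.protein_id for c in composites]
    parent = {pid: pid for pid in ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    coord_groups: dict[tuple, str] = {}
    seq_groups: dict[tuple, str] = {}
    for c in composites:
        g = by_gene.get(c.protein_id)
        if g is None:
            continue
        ck = (g.contig_id, g.start, g.end, g.strand)
        if ck in coord_groups:
            union(coord_groups[ck], c.protein_id)
        else:
            coord_groups[ck] = c.protein_id
        if g.protein_seq:
            sk = (g.contig_id, g.protein_seq)
            if sk in seq_groups:
                union(seq_groups[sk], c.protein_id)
            else:
                seq_groups[sk] = c.protein_id

    groups: dict[str, list[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), []).append(pid)
    keeper = {root: min(members) for root, members in groups.items()}
    for c in composites:
        if c.protein_id not in parent:
            c.duplicate_of = None
            continue
        keep = keeper[find(c.protein_id)]
        c.duplicate_of = None if c.protein_id == keep else keep
    return list(composites)


def survivors(composites: Iterable[CompositeProtein]) -> list[CompositeProtein]:
    """Records passing both filters (not excluded, not a duplicate)."""
    return [c for c in composites if not c.excluded_cellular and c.duplicate_of is None]


def categorize(
    composite: CompositeProtein,
    category_map: Sequence[tuple[str, str]] = tuple(DEFAULT_CATEGORY_MAP),
) -> str:
    """Assign a functional category from the keyword map (priority order).

    The first map keyword (case-insensitive substring on functional-hit
    names or accessions) that matches any functional hit assigns the
    category; no match yields unknown/DUF.
    """
    if not category_map:
        raise ValueError("category_map must be non-empty")
    for keyword, category in category_map:
        kw = keyword.upper()
        for hit in composite.functional_hits:
            if kw in hit.name.upper() or kw in hit.accession.upper():
                return category
    return UNKNOWN_CATEGORY


def categorize_all(
    composites: Sequence[CompositeProtein],
    category_map: Sequence[tuple[str, str]] = tuple(DEFAULT_CATEGORY_MAP),
) -> list[CompositeProtein]:
    for c in composites:
        c.category = categorize(c, category_map)
    return list(composites)


def annotation_share(
    composites: Sequence[CompositeProtein],
) -> tuple[int, int, float, float]:
    """(n_annotated, n_unknown, percent_annotated, percent_unknown).

    Percentages are reported to 1 decimal. Categories must be assigned.
    """
    if not composites:
        raise ValueError("no composites supplied")
    n_unknown = sum(1 for c in composites if c.category == UNKNOWN_CATEGORY)
    n_annotated = len(composites) - n_unknown
    total = len(composites)
    return (
        n_annotated,
        n_unknown,
        round(100.0 * n_annotated / total, 1),
        round(100.0 * n_unknown / total, 1),
    )


def read_category_map(path) -> list[tuple[str, str]]:
    """Load a keyword->category TSV (two columns, priority = file order)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            keyword, category = line.split("\t")[:2]
            out.append((keyword, category))
    if not out:
        raise ValueError(f"{path}: empty category map")
    return out
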