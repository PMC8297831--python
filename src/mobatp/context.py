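"""Gene-neighborhood conservation analysis around focal proteins.

The genomic context of a focal (composite ATPase) protein is the window of
k genes upstream and downstream by gene order on the contig (default 3).
Each position is scored by the number of distinct homologs of the occupying
protein (tabular homology hits at a stringent e-value cutoff, 1e-30 by
default), giving a 7-vector per focal protein. Hierarchical clustering of
these profiles separates the conserved-operon, conserved-pair and isolated
context types; a pairwise offset-agreement score quantifies gene-order
conservation across homologous foci, and coordinate-interval intersection
detects overlapping gene pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch

from mobatp.records import GeneRecord, HomologyHit

DEFAULT_CONTEXT_E_CUTOFF = 1e-30
CONTEXT_LABELS = ["context-rich", "pair-conserved", "isolated"]


@dataclass
class NeighborhoodProfile:
    """Homolog counts at gene offsets -k..+k around a focal protein."""

    focal_id: str
    neighbor_ids: list[Optional[str]]  # offset order, None = past contig edge
    homolog_counts: Optional[np.ndarray] = None  # NaN at missing positions
    small_neighbor: list[Optional[bool]] = field(default_factory=list)
    cluster_label: Optional[str] = None

    @property
    def k(self) -> int:
        return (len(self.neighbor_ids) - 1) // 2

    @property
    def offsets(self) -> list[int]:
        return list(range(-self.k, self.k + 1))

    def neighbor_at(self, offset: int) -> Optional[str]:
        return self.neighbor_ids[offset + self.k]


@dataclass
class OverlapPair:
    """Two genes on a contig whose coordinate intervals intersect."""

    gene_a: str
    gene_b: str
    overlap_bp: int


def build_neighborhood(
    genes: Sequence[GeneRecord], focal_id: str, k: int = 3
) -> NeighborhoodProfile:
    """Take the k genes up- and downstream of the focal by gene order.

    Neighbors are ranked by position along the contig (not bp distance);
    strand is ignored for membership. Positions past a contig edge are
    marked missing (None), not zero. Neighbors shorter than half the focal
    protein are flagged as small.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    contigs = {g.contig_id for g in ordered}
    if len(contigs) > 1:
        raise ValueError(f"genes span multiple contigs: {sorted(contigs)}")
    idx = next((i for i, g in enumerate(ordered) if g.gene_id == focal_id), None)
    if idx is None:
        raise ValueError(f"focal gene {focal_id} not on this contig")
    focal_len = len(ordered[idx].protein_seq)
    neighbor_ids: list[Optional[str]] = []
    small: list[Optional[bool]] = []
    for off in range(-k, k + 1):
        j = idx + off
        if 0 <= j < len(ordered):
            g = ordered[j]
            neighbor_ids.append(g.gene_id)
            if off == 0 or not focal_len or not g.protein_seq:
                small.append(None)
            else:
                small.append(len(g.protein_seq) < focal_len / 2)
        else:
            neighbor_ids.append(None)
            small.append(None)
    return NeighborhoodProfile(
        focal_id=focal_id, neighbor_ids=neighbor_ids, small_neighbor=small
    )


def count_homologs(
    protein_id: str,
    hits: Iterable[HomologyHit],
    e_cutoff: float = DEFAULT_CONTEXT_E_CUTOFF,
) -> int:
    """Distinct subjects hit by this protein at e <= cutoff, self excluded."""
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    subjects = {
        h.subject_id
        for h in hits
        if h.query_id == protein_id
        and h.subject_id != protein_id
        and h.e_value <= e_cutoff
    }
    return len(subjects)


def fill_homolog_counts(
    profiles: Sequence[NeighborhoodProfile],
    hits: Sequence[HomologyHit],
    e_cutoff: float = DEFAULT_CONTEXT_E_CUTOFF,
) -> list[NeighborhoodProfile]:
    """Set each profile's homolog-count vector from a homology hit table."""
    by_query: dict[str, set[str]] = {}
    for h in hits:
        if h.e_value <= e_cutoff and h.subject_id != h.query_id:
            by_query.setdefault(h.query_id, set()).add(h.subject_id)
    for p in profiles:
        counts = np.full(len(p.neighbor_ids), np.nan)
        for i, nid in enumerate(p.neighbor_ids):
            if nid is not None:
                counts[i] = len(by_query.get(nid, ()))
        p.homolog_counts = counts
    return list(profiles)


def build_context_matrix(
    profiles: Sequence[NeighborhoodProfile],
) -> tuple[np.ndarray, list[str]]:
    """Stack profiles into a (n_foci, 2k+1) matrix, NaN at missing positions.

    Rows are ordered by focal_id for stability.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    widths = {len(p.neighbor_ids) for p in profiles}
    if len(widths) != 1:
        raise ValueError("profiles have inconsistent window widths")
    for p in profiles:
        if p.homolog_counts is None:
            raise ValueError(f"profile {p.focal_id} has no homolog counts")
    ordered = sorted(profiles, key=lambda p: p.focal_id)
    matrix = np.vstack([p.homolog_counts for p in ordered])
    return matrix, [p.focal_id for p in ordered]


def _missing_aware_distances(matrix: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances over mutually present positions.

    Each pairwise distance is rescaled by coverage, sqrt(w / m) for m mutual
    positions out of w columns, so partially missing rows stay comparable.
    Pairs with no mutual positions get the matrix's maximum distance.
    """
    n, w = matrix.shape
    out = []
    for i, j in itertools.combinations(range(n), 2):
        mask = ~np.isnan(matrix[i]) & ~np.isnan(matrix[j])
        m = int(mask.sum())
        if m == 0:
            out.append(np.nan)
            continue
        d2 = float(np.sum((matrix[i, mask] - matrix[j, mask]) ** 2))
        out.append(np.sqrt(d2 * w / m))
    dist = np.asarray(out)
    if np.isnan(dist).any():
        fill = np.nanmax(dist) if np.isfinite(np.nanmax(dist)) else 1.0
        dist = np.where(np.isnan(dist), fill, dist)
    return dist


def cluster_contexts(
    matrix: np.ndarray,
    n_clusters: int = 3,
    linkage: str = "ward",
    log1p: bool = True,
) -> list[str]:
    """Agglomerative clustering of context profiles into labelled types.

    Hierarchical clustering on missing-aware Euclidean distances; counts are
    log1p-compressed by default so a single huge family cannot dominate.
    Ward linkage is the default because it resists splitting off singleton
    outlier profiles at small cluster counts; average/complete are available
    for conventional heatmap-style trees. Clusters are labelled
    deterministically by mean total homolog count, descending: with k=3 that
    yields context-rich, pair-conserved and isolated; other k get rank names.
    """
    matrix = np.asarray(matrix, dtype=float)
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if matrix.shape[0] < n_clusters:
        raise ValueError(
            f"{matrix.shape[0]} rows cannot form {n_clusters} clusters"
        )
    data = np.log1p(matrix) if log1p else matrix
    dist = _missing_aware_distances(data)
    tree = sch.linkage(dist, method=linkage)
    assignments = sch.fcluster(tree, t=n_clusters, criterion="maxclust")
    totals = np.nansum(data, axis=1)
    means = {
        c: float(np.mean(totals[assignments == c])) for c in np.unique(assignments)
    }
    # deterministic: rank clusters by mean total count, descending
    ranked = sorted(means, key=lambda c: (-means[c], c))
    if n_clusters == 3 and len(ranked) == 3:
        names = dict(zip(ranked, CONTEXT_LABELS))
    else:
        names = {c: f"cluster-{r}" for r, c in enumerate(ranked)}
    return [names[c] for c in assignments]


def order_conservation_score(
    profiles: Sequence[NeighborhoodProfile],
    homology: Iterable[HomologyHit],
    e_cutoff: float = DEFAULT_CONTEXT_E_CUTOFF,
) -> Optional[float]:
    """Fraction of homologous neighbor pairs sitting at the same signed offset.

    For every pair of profiles (whose foci are homologous), neighbors are
    matched across the pair by homology; the per-pair score is the fraction
    of matched pairs occupying the same offset, and the result averages over
    profile pairs with at least one match. Returns None when no neighbor
    homology exists at all (undefined).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    related: set[frozenset[str]] = set()
    for h in homology:
        if h.e_value <= e_cutoff and h.query_id != h.subject_id:
            related.add(frozenset((h.query_id, h.subject_id)))

    pair_scores = []
    for pa, pb in itertools.combinations(profiles, 2):
        same = total = 0
        for off_a in pa.offsets:
            if off_a == 0:
                continue
            a = pa.neighbor_at(off_a)
            if a is None:
                continue
            for off_b in pb.offsets:
                if off_b == 0:
                    continue
                b = pb.neighbor_at(off_b)
                if b is None or frozenset((a, b)) not in related:
                    continue
                total += 1
                if off_a == off_b:
                    same += 1
        if total:
            pair_scores.append(same / total)
    if not pair_scores:
        return None
    return float(np.mean(pair_scores))


def detect_overlaps(
    genes: Sequence[GeneRecord], focal_id: str
) -> list[OverlapPair]:
    """Pairs (focal, neighbor) whose coordinate intervals intersect >= 1 bp.

    Strand is ignored; abutting genes do not overlap. Symmetric in the pair
    by construction of the intersection.
    """
    focal = next((g for g in genes if g.gene_id == focal_id), None)
    if focal is None:
        raise ValueError(f"focal gene {focal_id} not found")
    pairs = []
    for g in genes:
        if g.gene_id == focal_id or g.contig_id != focal.contig_id:
            continue
        lo = max(focal.start, g.start)
        hi = min(focal.end, g.end)
        if hi >= lo:
            pairs.append(
                OverlapPair(gene_a=focal_id, gene_b=g.gene_id, overlap_bp=hi - lo + 1)
            )
    pairs.sort(key=lambda p: p.gene_b)
    return pairs
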