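"""Neighborhood profiles, homolog counting, context clustering, overlaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobatp.context import (
    CONTEXT_LABELS,
    build_context_matrix,
    build_neighborhood,
    cluster_contexts,
    count_homologs,
    detect_overlaps,
    fill_homolog_counts,
    order_conservation_score,
)
from mobatp.records import GeneRecord, HomologyHit


def contig(n, contig_id="c1", gene_len=300, gap=50, prefix="g"):
    genes, cursor = [], 1
    for i in range(n):
        genes.append(
            GeneRecord(contig_id, f"{prefix}{i}", cursor, cursor + gene_len - 1, "+")
        )
        cursor += gene_len + gap
    return genes


def hh(q, s, e=1e-40):
    return HomologyHit(q, s, e, 400.0)


class TestBuildNeighborhood:
    def test_mid_contig_window(self):
        genes = contig(9)
        p = build_neighborhood(genes, "g4", k=3)
        assert p.neighbor_ids == [f"g{i}" for i in range(1, 8)]
        assert p.neighbor_at(0) == "g4" and p.neighbor_at(-3) == "g1"

    def test_contig_edge_marked_missing(self):
        genes = contig(5)
        p = build_neighborhood(genes, "g1", k=3)
        assert p.neighbor_ids == [None, None, "g0", "g1", "g2", "g3", "g4"]

    def test_single_gene_contig(self):
        p = build_neighborhood(contig(1), "g0", k=3)
        assert p.neighbor_ids == [None, None, None, "g0", None, None, None]

    def test_focal_absent_rejected(self):
        with pytest.raises(ValueError, match="gX"):
            build_neighborhood(contig(3), "gX")

    def test_multiple_contigs_rejected(self):
        genes = contig(2) + contig(2, contig_id="c2", prefix="h")
        with pytest.raises(ValueError, match="multiple contigs"):
            build_neighborhood(genes, "g0")

    def test_small_neighbor_flag(self):
        genes = contig(3)
        genes[1].protein_seq = "M" * 100  # focal
        genes[0].protein_seq = "M" * 40  # < half focal
        genes[2].protein_seq = "M" * 80
        p = build_neighborhood(genes, "g1", k=1)
        assert p.small_neighbor == [True, None, False]

    @settings(derandomize=True, max_examples=60)
    @given(
        st.integers(min_value=1, max_value=12),
        st.integers(min_value=0, max_value=11),
        st.integers(min_value=1, max_value=4),
    )
    def test_mirrored_contig_reverses_window(self, n, fi, k):
        fi = fi % n
        genes = contig(n)
        span = max(g.end for g in genes) + 1
        mirrored = [
            GeneRecord(g.contig_id, g.gene_id, span - g.end, span - g.start, g.strand)
            for g in genes
        ]
        fwd = build_neighborhood(genes, f"g{fi}", k=k)
        rev = build_neighborhood(mirrored, f"g{fi}", k=k)
        assert rev.neighbor_ids == fwd.neighbor_ids[::-1]


class TestCountHomologs:
    def test_distinct_subjects_under_cutoff(self):
        hits = [
            hh("p", "s1", 1e-40),
            hh("p", "s2", 1e-35),
            hh("p", "s2", 1e-32),  # duplicate subject
            hh("p", "s3", 1e-20),  # above 1e-30 cutoff
            hh("q", "s4", 1e-40),  # different query
        ]
        assert count_homologs("p", hits) == 2

    def test_self_hit_excluded(self):
        assert count_homologs("p", [hh("p", "p", 0.0)]) == 0

    def test_empty_table(self):
        assert count_homologs("p", []) == 0

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            count_homologs("p", [], e_cutoff=0.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2", "s3", "s4"]),
                st.floats(min_value=1e-60, max_value=1e-10),
            ),
            max_size=15,
        ),
        st.floats(min_value=1e-50, max_value=1e-20),
        st.floats(min_value=1e-50, max_value=1e-20),
    )
    def test_monotone_in_cutoff(self, rows, c1, c2):
        hits = [hh("p", s, e) for s, e in rows]
        lo, hi = sorted([c1, c2])
        assert count_homologs("p", hits, lo) <= count_homologs("p", hits, hi)


class TestContextMatrix:
    def test_nan_at_missing_not_zero(self):
        genes = contig(5)
        profiles = [build_neighborhood(genes, f"g{i}") for i in (0, 2, 4)]
        hits = [hh(f"g{i}", f"s{j}") for i in range(5) for j in range(2)]
        fill_homolog_counts(profiles, hits)
        matrix, ids = build_context_matrix(profiles)
        assert matrix.shape == (3, 7)
        assert ids == ["g0", "g2", "g4"]
        assert np.isnan(matrix[0, 0]) and np.isnan(matrix[0, 1])  # past left edge
        assert matrix[1, 3] == 2.0  # present positions are counts, not NaN

    def test_unfilled_profile_rejected(self):
        profiles = [build_neighborhood(contig(3), "g1")]
        with pytest.raises(ValueError, match="homolog counts"):
            build_context_matrix(profiles)


class TestClusterContexts:
    def test_recovers_planted_templates(self):
        rich = [9.0] * 7
        pair = [0.0, 0.0, 0.0, 9.0, 9.0, 0.0, 0.0]
        iso = [0.0] * 7
        matrix = np.array([rich] * 10 + [pair] * 10 + [iso] * 10)
        truth = ["context-rich"] * 10 + ["pair-conserved"] * 10 + ["isolated"] * 10
        labels = cluster_contexts(matrix)
        assert labels == truth

    def test_label_order_by_mean_total(self):
        matrix = np.array([[9.0] * 7, [9.0] * 7, [1.0] * 7, [0.0] * 7])
        labels = cluster_contexts(matrix, n_clusters=3)
        assert labels[0] == labels[1] == CONTEXT_LABELS[0]
        assert set(labels) == set(CONTEXT_LABELS)

    def test_missing_positions_tolerated(self):
        rich = [9.0] * 7
        rich_trunc = [np.nan, np.nan, 9.0, 9.0, 9.0, 9.0, 9.0]
        iso = [0.0] * 7
        matrix = np.array([rich] * 5 + [rich_trunc] * 5 + [iso] * 5)
        labels = cluster_contexts(matrix, n_clusters=2)
        assert labels[:10] == [labels[0]] * 10
        assert labels[10] != labels[0]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_contexts(np.zeros((2, 7)), n_clusters=3)

    def test_full_pipeline_agreement_on_generated_data(self, sim_default):
        by_contig = sim_default.genes_by_contig(dedup=True)
        truth_ctx = sim_default.truth.context
        profiles = []
        for fid, info in sorted(truth_ctx.items()):
            if fid in sim_default.truth.duplicates:
                continue
            profiles.append(build_neighborhood(by_contig[info["genome"]], fid))
        fill_homolog_counts(profiles, sim_default.homology)
        matrix, ids = build_context_matrix(profiles)
        labels = cluster_contexts(matrix)
        name = {
            "conserved_operon": "context-rich",
            "conserved_pair": "pair-conserved",
            "isolated": "isolated",
        }
        truth = [name[truth_ctx[f]["type"]] for f in ids]
        agreement = np.mean([p == t for p, t in zip(labels, truth)])
        assert agreement >= 0.9


class TestOrderConservation:
    def _profiles(self):
        ga, gb = contig(7, prefix="a"), contig(7, contig_id="c2", prefix="b")
        pa = build_neighborhood(ga, "a3")
        pb = build_neighborhood(gb, "b3")
        return pa, pb

    def test_identical_operons_score_one(self):
        pa, pb = self._profiles()
        homology = [hh(f"a{i}", f"b{i}") for i in range(7)]
        assert order_conservation_score([pa, pb], homology) == pytest.approx(1.0)

    def test_mixed_offsets_fraction(self):
        pa, pb = self._profiles()
        # a4 <-> b4 at same offset (+1/+1); a2 <-> b5 at offsets -1 vs +2
        homology = [hh("a4", "b4"), hh("a2", "b5")]
        assert order_conservation_score([pa, pb], homology) == pytest.approx(0.5)

    def test_enumeration_oracle_on_shuffled_links(self):
        pa, pb = self._profiles()
        links = [("a1", "b5"), ("a2", "b2"), ("a4", "b4"), ("a6", "b1"), ("a5", "b6")]
        homology = [hh(a, b) for a, b in links]
        # brute-force oracle: same signed offset relative to the foci a3/b3
        same = total = 0
        for a, b in links:
            total += 1
            if int(a[1]) - 3 == int(b[1]) - 3:
                same += 1
        assert order_conservation_score([pa, pb], homology) == pytest.approx(same / total)

    def test_no_neighbor_homology_is_undefined(self):
        pa, pb = self._profiles()
        assert order_conservation_score([pa, pb], [hh("a3", "b3")]) is None

    def test_fewer_than_two_profiles_rejected(self):
        pa, _ = self._profiles()
        with pytest.raises(ValueError):
            order_conservation_score([pa], [])

    def test_generator_operon_families_fully_conserved(self, sim_default):
        by_contig = sim_default.genes_by_contig(dedup=True)
        families = {}
        for fid, info in sim_default.truth.context.items():
            if info["type"] == "conserved_operon" and info["family"]:
                families.setdefault(info["family"], []).append((fid, info["genome"]))
        checked = 0
        for members in families.values():
            if len(members) < 2:
                continue
            profiles = [
                build_neighborhood(by_contig[gid], fid) for fid, gid in members
            ]
            score = order_conservation_score(profiles, sim_default.homology)
            assert score == pytest.approx(1.0)
            checked += 1
        assert checked >= 3


class TestDetectOverlaps:
    def test_intersection_length(self):
        genes = [
            GeneRecord("c1", "f", 100, 400, "+"),
            GeneRecord("c1", "n", 380, 700, "-"),
        ]
        pairs = detect_overlaps(genes, "f")
        assert len(pairs) == 1 and pairs[0].overlap_bp == 21

    def test_abutting_genes_do_not_overlap(self):
        genes = [
            GeneRecord("c1", "f", 100, 400, "+"),
            GeneRecord("c1", "n", 401, 700, "+"),
        ]
        assert detect_overlaps(genes, "f") == []

    def test_nested_gene_full_length(self):
        genes = [
            GeneRecord("c1", "f", 100, 400, "+"),
            GeneRecord("c1", "n", 200, 250, "+"),
        ]
        assert detect_overlaps(genes, "f")[0].overlap_bp == 51

    def test_symmetric_in_focal_choice(self):
        genes = [
            GeneRecord("c1", "f", 100, 400, "+"),
            GeneRecord("c1", "n", 380, 700, "-"),
        ]
        a = detect_overlaps(genes, "f")[0]
        b = detect_overlaps(genes, "n")[0]
        assert a.overlap_bp == b.overlap_bp

    def test_other_contig_ignored(self):
        genes = [
            GeneRecord("c1", "f", 100, 400, "+"),
            GeneRecord("c2", "n", 100, 400, "+"),
        ]
        assert detect_overlaps(genes, "f") == []

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError):
            detect_overlaps([], "f")

    def test_generator_pairs_overlap_by_20bp(self, sim_default):
        by_contig = sim_default.genes_by_contig(dedup=True)
        checked = 0
        for fid, info in sim_default.truth.context.items():
            if info["type"] == "conserved_pair" and info["overlap"]:
                pairs = detect_overlaps(by_contig[info["genome"]], fid)
                assert any(
                    p.gene_b == info["partner"] and p.overlap_bp == 20 for p in pairs
                )
                checked += 1
        assert checked >= 3
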