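"""Composite detection, cellular exclusion, deduplication, categorization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobatp.composites import (
    UNKNOWN_CATEGORY,
    annotation_share,
    categorize,
    categorize_all,
    deduplicate,
    detect_composites,
    exclude_cellular_contigs,
    survivors,
)
from mobatp.records import ContigTaxonomy, DomainHit, GeneRecord


def gene(pid, contig="c1", start=1, end=300, strand="+", seq=""):
    return GeneRecord(contig, pid, start, end, strand, seq)


def hit(pid, name, e=1e-10, span=(1, 50)):
    return DomainHit(pid, "PF00001", name, e, *span)


def composite(pid, functional_names=("PIN_4",), contig="c1"):
    c = detect_composites(
        [gene(pid, contig)],
        [hit(pid, "AAA_22")] + [hit(pid, n, span=(60, 110)) for n in functional_names],
    )
    assert len(c) == 1
    return c[0]


class TestDetectComposites:
    def test_atpase_plus_functional_is_composite(self):
        out = detect_composites(
            [gene("p1")], [hit("p1", "AAA_22"), hit("p1", "PIN_4", span=(60, 110))]
        )
        assert len(out) == 1
        assert [h.name for h in out[0].atpase_hits] == ["AAA_22"]
        assert [h.name for h in out[0].functional_hits] == ["PIN_4"]

    def test_atpase_only_is_not_composite(self):
        assert detect_composites([gene("p1")], [hit("p1", "AAA_22")]) == []

    def test_functional_only_is_not_composite(self):
        assert detect_composites([gene("p1")], [hit("p1", "PIN_4")]) == []

    def test_weak_functional_hit_ignored(self):
        out = detect_composites(
            [gene("p1")], [hit("p1", "AAA_22"), hit("p1", "PIN_4", e=0.1)]
        )
        assert out == []

    def test_two_candidates_sorted_by_id(self):
        genes = [gene("pB"), gene("pA", contig="c2")]
        hits = [
            hit("pB", "AAA_22"), hit("pB", "DEAD", span=(60, 110)),
            hit("pA", "ATPase_2"), hit("pA", "Lon_C", span=(60, 110)),
        ]
        out = detect_composites(genes, hits)
        assert [c.protein_id for c in out] == ["pA", "pB"]
        assert out[0].contig_id == "c2"

    def test_matches_generator_truth(self, sim_small):
        out = detect_composites(sim_small.genes, sim_small.domain_hits)
        assert {c.protein_id for c in out} == sim_small.truth.composite_ids()


class TestCellularExclusion:
    def test_majority_cellular_excluded(self):
        comps = [composite("p1", contig="cA"), composite("p2", contig="cB")]
        tax = [ContigTaxonomy("cA", 10, 6), ContigTaxonomy("cB", 10, 4)]
        out = exclude_cellular_contigs(comps, tax)
        flags = {c.protein_id: c.excluded_cellular for c in out}
        assert flags == {"p1": True, "p2": False}

    def test_exactly_half_is_retained(self):
        comps = [composite("p1", contig="cA")]
        out = exclude_cellular_contigs(comps, [ContigTaxonomy("cA", 10, 5)])
        assert out[0].excluded_cellular is False

    def test_missing_taxonomy_rejected(self):
        with pytest.raises(ValueError, match="cX"):
            exclude_cellular_contigs(
                [composite("p1", contig="cX")], [ContigTaxonomy("cA", 10, 5)]
            )

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            exclude_cellular_contigs([], [], threshold=1.0)


class TestDeduplicate:
    def test_coordinate_duplicates_collapse_to_smallest_id(self):
        genes = [
            gene("pA", start=100, end=400),
            gene("pC", start=100, end=400),
            gene("pB", start=100, end=400),
        ]
        comps = [composite(p) for p in ("pA", "pC", "pB")]
        out = deduplicate(comps, genes)
        kept = {c.protein_id: c.duplicate_of for c in out}
        assert kept == {"pA": None, "pB": "pA", "pC": "pA"}

    def test_sequence_identity_on_same_contig_is_duplicate(self):
        genes = [
            gene("pA", start=100, end=400, seq="MKV"),
            gene("pB", start=900, end=1200, seq="MKV"),
        ]
        out = deduplicate([composite("pA"), composite("pB")], genes)
        assert {c.protein_id: c.duplicate_of for c in out} == {"pA": None, "pB": "pA"}

    def test_same_sequence_different_contig_not_duplicate(self):
        genes = [
            gene("pA", contig="c1", seq="MKV"),
            gene("pB", contig="c2", seq="MKV"),
        ]
        out = deduplicate(
            [composite("pA", contig="c1"), composite("pB", contig="c2")], genes
        )
        assert all(c.duplicate_of is None for c in out)

    def test_idempotent(self):
        genes = [gene("pA", start=1, end=300), gene("pB", start=1, end=300)]
        comps = [composite("pA"), composite("pB")]
        once = {c.protein_id: c.duplicate_of for c in deduplicate(comps, genes)}
        twice = {c.protein_id: c.duplicate_of for c in deduplicate(comps, genes)}
        assert once == twice == {"pA": None, "pB": "pA"}

    def test_matches_generator_truth(self, sim_small):
        comps = detect_composites(sim_small.genes, sim_small.domain_hits)
        deduplicate(comps, sim_small.genes)
        called = {c.protein_id for c in comps if c.duplicate_of is not None}
        # every planted duplicate whose original is composite must be collapsed
        planted = {
            d for d, o in sim_small.truth.duplicates.items()
            if o in sim_small.truth.composite_ids()
        }
        assert planted <= called


class TestCategorize:
    @pytest.mark.parametrize(
        "names,expected",
        [
            (("LAGLIDADG_1",), "nuclease"),
            (("Peptidase_S14",), "protease"),
            (("SNF2_N",), "helicase"),
            (("DUF2791",), UNKNOWN_CATEGORY),
            (("DUF2791", "Terminase_6"), "transport/packaging"),
        ],
    )
    def test_examples(self, names, expected):
        assert categorize(composite("p1", functional_names=names)) == expected

    def test_priority_order_first_keyword_wins(self):
        # PIN (nuclease) precedes ABC (transport) in the default map
        c = composite("p1", functional_names=("ABC_membrane", "PIN_4"))
        assert categorize(c) == "nuclease"

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            categorize(composite("p1"), category_map=[])

    def test_matches_generator_truth(self, sim_small):
        comps = categorize_all(
            detect_composites(sim_small.genes, sim_small.domain_hits)
        )
        labels = sim_small.truth.atpase_proteins
        for c in comps:
            assert c.category == labels[c.protein_id]["category"]


class TestAnnotationShare:
    def test_rounding_to_one_decimal(self):
        comps = [composite(f"p{i}") for i in range(3)]
        comps[0].category = "nuclease"
        comps[1].category = "helicase"
        comps[2].category = UNKNOWN_CATEGORY
        assert annotation_share(comps) == (2, 1, 66.7, 33.3)

    def test_all_unknown(self):
        comps = [composite("p1")]
        comps[0].category = UNKNOWN_CATEGORY
        assert annotation_share(comps) == (0, 1, 0.0, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            annotation_share([])


class TestFilterAlgebra:
    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_exclusion_and_dedup_commute(self, data):
        n = data.draw(st.integers(min_value=2, max_value=8))
        coords = data.draw(
            st.lists(st.integers(min_value=0, max_value=3), min_size=n, max_size=n)
        )
        cellular = data.draw(
            st.lists(st.integers(min_value=0, max_value=10), min_size=n, max_size=n)
        )
        # genes sharing a coordinate slot on one contig are duplicates
        genes2 = [
            GeneRecord("shared", f"p{i}", 1 + 500 * c, 300 + 500 * c, "+")
            for i, c in enumerate(coords)
        ]
        comps_a = [composite(f"p{i}", contig="shared") for i in range(n)]
        comps_b = [composite(f"p{i}", contig="shared") for i in range(n)]
        tax_shared = [ContigTaxonomy("shared", 10, cellular[0])]

        surv_a = {
            c.protein_id
            for c in survivors(
                deduplicate(exclude_cellular_contigs(comps_a, tax_shared), genes2)
            )
        }
        surv_b = {
            c.protein_id
            for c in survivors(
                exclude_cellular_contigs(deduplicate(comps_b, genes2), tax_shared)
            )
        }
        assert surv_a == surv_b

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-30, max_value=1e-3), st.floats(min_value=1e-30, max_value=1e-3))
    def test_detection_monotone_in_cutoff(self, c1, c2):
        lo, hi = sorted([c1, c2])
        hits = [
            hit("p1", "AAA_22", e=1e-20),
            hit("p1", "PIN_4", e=1e-8, span=(60, 110)),
            hit("p2", "ATPase_2", e=1e-5),
            hit("p2", "DEAD", e=1e-4, span=(60, 110)),
        ]
        genes = [gene("p1"), gene("p2", contig="c2")]
        ids_lo = {c.protein_id for c in detect_composites(genes, hits, e_cutoff=lo)}
        ids_hi = {c.protein_id for c in detect_composites(genes, hits, e_cutoff=hi)}
        assert ids_lo <= ids_hi
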