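"""Hypergeometric tails, BH-FDR, over-representation and category tallies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netpharm.enrichment import (
    bh_fdr,
    classify_categories,
    enrich,
    hypergeom_tail,
)
from netpharm.errors import UsageError
from netpharm.model import AnnotationCollection
from netpharm.simulate import generate_annotations

from _oracles import brute_bh, exact_hypergeom_tail


class TestHypergeomTail:
    def test_hand_computed_example(self):
        # P(X >= 4) with K=5, n=4, N=10 = C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_tail(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_zero_overlap_is_whole_tail(self):
        assert hypergeom_tail(0, 5, 4, 10) == 1.0

    def test_ease_decrements_overlap(self):
        assert hypergeom_tail(1, 5, 4, 10, ease=True) == 1.0
        assert hypergeom_tail(5, 8, 6, 30, ease=True) == pytest.approx(
            hypergeom_tail(4, 8, 6, 30)
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(UsageError):
            hypergeom_tail(5, 4, 6, 10)
        with pytest.raises(UsageError):
            hypergeom_tail(2, 4, 6, 5)

    @pytest.mark.parametrize("N", [12, 23, 37])
    def test_matches_exact_rational_summation(self, N):
        for K in range(0, N + 1, 3):
            for n in range(1, N + 1, 4):
                for k in range(0, min(K, n) + 1):
                    expected = float(exact_hypergeom_tail(k, K, n, N))
                    assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, abs=1e-12)


class TestBhFdr:
    def test_hand_bh(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_empty_input(self):
        assert bh_fdr([]) == []

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=80)
    def test_bounds_and_permutation_invariance(self, ps):
        adjusted = bh_fdr(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, ps))
        assert all(a <= 1.0 + 1e-12 for a in adjusted)
        assert adjusted == pytest.approx(brute_bh(ps), abs=1e-12)
        # permutation invariance after mapping back
        perm = list(reversed(range(len(ps))))
        re_adj = bh_fdr([ps[i] for i in perm])
        assert [re_adj[perm.index(i)] for i in range(len(ps))] == pytest.approx(adjusted)


def _toy_annotation():
    rng = np.random.default_rng(1)
    universe = [f"G{i:03d}" for i in range(200)]
    terms = {}
    for t in range(20):
        members = universe[t * 10:(t + 1) * 10]
        terms[f"T{t:02d}"] = (f"term {t}", "GO_BP", members)
    return AnnotationCollection.from_terms(terms, universe=universe)


class TestEnrich:
    def test_full_term_query_ranks_first_and_passes(self):
        ann = _toy_annotation()
        query = sorted(ann.terms["T03"][2])
        results = enrich(query, ann)
        assert results[0].term_id == "T03"
        # oracle: the exact tail for a full overlap
        expected = float(exact_hypergeom_tail(10, 10, 10, 200))
        assert results[0].p_value == pytest.approx(expected, rel=1e-9)
        assert results[0].passes

    def test_rich_factor_definition(self):
        ann = _toy_annotation()
        query = sorted(ann.terms["T00"][2])[:5] + ["G199"]
        results = enrich(query, ann)
        top = next(r for r in results if r.term_id == "T00")
        assert top.k == 5 and top.K == 10
        assert top.rich_factor == pytest.approx(0.5)

    def test_zero_overlap_terms_not_reported(self):
        ann = _toy_annotation()
        results = enrich(sorted(ann.terms["T00"][2]), ann)
        assert {r.term_id for r in results} == {"T00"}

    def test_query_outside_background_rejected(self):
        ann = _toy_annotation()
        with pytest.raises(UsageError):
            enrich(["NOPE"], ann)

    def test_fdr_within_category(self):
        # identical overlap pattern in two categories must adjust independently
        universe = [f"G{i}" for i in range(40)]
        terms = {
            "A1": ("a1", "GO", universe[:10]),
            "A2": ("a2", "GO", universe[10:20]),
            "B1": ("b1", "KEGG", universe[:10]),
        }
        ann = AnnotationCollection.from_terms(terms, universe=universe)
        results = {r.term_id: r for r in enrich(universe[:10], ann, p_threshold=1.0,
                                                fdr_threshold=1.0)}
        # B1 is alone in its category: its FDR equals its p-value
        assert results["B1"].fdr == pytest.approx(results["B1"].p_value)

    def test_null_queries_calibrated(self):
        # fraction of null term tests with p < 0.01 should be close to 0.01
        rng = np.random.default_rng(2024)
        universe = [f"G{i:04d}" for i in range(4000)]
        ann, _ = generate_annotations(
            n_terms=10, term_size_range=(800, 800), universe=universe, seed=77,
        )
        hits = total = 0
        for _ in range(200):
            query = rng.choice(universe, size=600, replace=False)
            for r in enrich(query, ann, p_threshold=1.0, fdr_threshold=1.0):
                hits += r.p_value < 0.01
                total += 1
        frac = hits / total
        # binomial 99% band around 0.01 at this sample size
        half = 2.58 * np.sqrt(0.01 * 0.99 / total)
        assert 0.01 - half < frac < 0.01 + half


class TestClassifyCategories:
    def test_tally_sums_to_total_passing(self):
        ann = _toy_annotation()
        query = sorted(ann.terms["T00"][2]) + sorted(ann.terms["T05"][2])
        results = enrich(query, ann)
        cmap = {"T00": "cellular processes", "T05": "human diseases"}
        tally = classify_categories(results, cmap)
        assert sum(tally.values()) == sum(r.passes for r in results)

    def test_unmapped_terms_fall_in_unassigned(self):
        ann = _toy_annotation()
        results = enrich(sorted(ann.terms["T01"][2]), ann)
        tally = classify_categories(results, {})
        assert tally == {"unassigned": 1}

    def test_empty_results_empty_tally(self):
        assert classify_categories([]) == {}

    def test_toy_map_hand_count(self):
        ann = _toy_annotation()
        query = sorted(set().union(*[ann.terms[f"T{t:02d}"][2] for t in range(3)]))
        results = enrich(query, ann)
        cmap = {"T00": "metabolism", "T01": "metabolism", "T02": "signaling"}
        tally = classify_categories(results, cmap)
        assert tally["metabolism"] == 2 and tally["signaling"] == 1
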