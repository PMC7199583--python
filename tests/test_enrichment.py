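from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megapath.enrichment import (
    bh_fdr,
    filter_and_rank,
    fisher_enrich,
    fisher_pvalue,
    genes_covered,
    jaccard,
)
from megapath.formats_io import GeneSetCollection
from megapath.synthetic_data import TOP10_SET_GEOMETRY, simulate_genesets

#: published top-10 arithmetic: (set size, overlap with a 26-gene query) -> J
PUBLISHED_JACCARD = [
    (544, 17, 0.031), (334, 14, 0.040), (803, 17, 0.021), (662, 16, 0.024),
    (553, 15, 0.027), (215, 12, 0.052), (424, 14, 0.032), (603, 15, 0.024),
    (461, 14, 0.030), (630, 15, 0.023),
]


class TestJaccard:
    @pytest.mark.parametrize("set_size,overlap,expected", PUBLISHED_JACCARD)
    def test_published_values_to_three_decimals(self, set_size, overlap, expected):
        assert round(jaccard(set_size, 26, overlap), 3) == expected

    def test_identity_and_zero_conventions(self):
        assert jaccard(7, 7, 7) == 1.0
        assert jaccard(0, 0, 0) == 0.0
        assert jaccard(5, 3, 0) == 0.0

    def test_overlap_exceeding_size_is_error(self):
        with pytest.raises(ValueError):
            jaccard(3, 2, 4)


class TestFisher:
    def test_small_universe_hand_oracle(self):
        # universe 10, set of 3, query of 2, overlap 2 -> C(3,2)/C(10,2)
        assert fisher_pvalue(10, 3, 2, 2) == pytest.approx(3 / 45, abs=1e-12)

    def test_disjoint_query_and_degenerate_cases(self):
        assert fisher_pvalue(10, 3, 2, 0) == pytest.approx(1.0)
        assert fisher_pvalue(8, 8, 8, 8) == pytest.approx(1.0)

    @given(st.integers(4, 12), st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_enumeration(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, min(N, 6)))
        x = data.draw(st.integers(0, min(K, n)))
        # enumerate all n-subsets of the universe, count overlap >= x
        universe = range(N)
        successes = set(range(K))
        hits = sum(
            1 for q in combinations(universe, n) if len(successes & set(q)) >= x
        )
        assert fisher_pvalue(N, K, n, x) == pytest.approx(
            hits / comb(N, n), abs=1e-12
        )

    @given(st.integers(50, 500), st.integers(5, 30))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing_in_overlap(self, K, n):
        N = 1000
        ps = [fisher_pvalue(N, K, n, x) for x in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestBhFdr:
    def test_hand_oracle(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.randoms())
    @settings(max_examples=40, deadline=None)
    def test_order_invariance_and_stepup_oracle(self, ps, random):
        qs = bh_fdr(ps)
        # hand step-up oracle
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = running
        assert qs == pytest.approx(expected, abs=1e-12)
        perm = list(range(m))
        random.shuffle(perm)
        qs_perm = bh_fdr([ps[i] for i in perm])
        assert qs_perm == pytest.approx([qs[i] for i in perm], abs=1e-12)


class TestEnrich:
    @pytest.fixture
    def collection(self):
        sets = {
            "hit": frozenset({"A", "B", "C", "U1"}),
            "miss": frozenset({"U2", "U3", "U4"}),
        }
        universe = frozenset({"A", "B", "C"} | {f"U{i}" for i in range(1, 8)})
        return GeneSetCollection(sets=sets, universe=universe)

    def test_results_carry_counts_q_and_jaccard(self, collection):
        results = fisher_enrich(["A", "B", "C"], collection)
        by_name = {r.set_name: r for r in results}
        hit = by_name["hit"]
        assert (hit.set_size, hit.query_size, hit.overlap) == (4, 3, 3)
        assert hit.jaccard == pytest.approx(3 / 4)
        assert hit.q_value >= hit.p_value
        assert by_name["miss"].overlap == 0
        assert by_name["miss"].p_value == pytest.approx(1.0)

    def test_sorted_by_p_then_name(self, collection):
        results = fisher_enrich(["A", "B", "C"], collection)
        keys = [(r.p_value, r.set_name) for r in results]
        assert keys == sorted(keys)

    def test_query_outside_universe_dropped_with_warning(self, collection, caplog):
        with caplog.at_level("WARNING"):
            results = fisher_enrich(["A", "B", "NOTTHERE"], collection)
        assert results[0].query_size == 2
        assert any("outside the universe" in r.message for r in caplog.records)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrich(["A"], GeneSetCollection(sets={}))


class TestFilterRankCoverage:
    def make(self, name, p, overlap_genes=()):
        from megapath.enrichment import EnrichmentResult

        return EnrichmentResult(
            set_name=name, go_id="", set_size=10, query_size=5,
            overlap=len(overlap_genes), p_value=p,
            jaccard=jaccard(10, 5, len(overlap_genes)),
            overlap_genes=frozenset(overlap_genes),
        )

    def test_threshold_and_topk(self):
        results = [self.make(f"S{i}", p) for i, p in enumerate([1e-8, 1e-3, 1e-7])]
        kept = filter_and_rank(results, p_threshold=1e-6)
        assert [r.set_name for r in kept] == ["S0", "S2"]
        assert len(filter_and_rank(results, top_k=2)) == 2

    def test_ties_broken_by_name_deterministically(self):
        results = [self.make(n, 1e-4) for n in ("b", "a", "c")]
        assert [r.set_name for r in filter_and_rank(results)] == ["a", "b", "c"]

    def test_coverage_counts_union_of_overlaps(self):
        query = ["A", "B", "C", "D"]
        assert genes_covered([], query) == 0
        full = self.make("S", 1e-9, overlap_genes=("A", "B", "C", "D"))
        assert genes_covered([full], query) == 4
        partial = [
            self.make("S1", 1e-9, overlap_genes=("A",)),
            self.make("S2", 1e-9, overlap_genes=("A", "B")),
        ]
        assert genes_covered(partial, query) == 2

    def test_planted_coverage_recovered(self):
        query = [f"Q{i:02d}" for i in range(26)]
        collection, _ = simulate_genesets(
            n_sets=10, size_range=(40, 60), planted_query=query,
            planted_overlaps=[12], universe_size=500, seed=3,
            coverage_pool=query[:24],
        )
        results = fisher_enrich(query, collection)
        assert genes_covered(results, query) == 24


class TestPublishedGeometry:
    def test_planted_top10_reproduces_published_jaccard(self):
        query = [f"Q{i:02d}" for i in range(26)]
        collection, truth = simulate_genesets(
            n_sets=10, size_range=(0, 0), planted_query=query,
            planted_overlaps=[0], universe_size=8000, seed=9,
            geometry=TOP10_SET_GEOMETRY,
        )
        assert len(truth) == 10
        for name, _, size, overlap in TOP10_SET_GEOMETRY:
            expected = next(
                j for s, o, j in PUBLISHED_JACCARD if (s, o) == (size, overlap)
            )
            assert round(jaccard(size, 26, overlap), 3) == expected
            assert len(collection.sets[name]) == size
            assert len(collection.sets[name] & set(query)) == overlap
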