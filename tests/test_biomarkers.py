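"""Intersection calling, composite FDR arithmetic, and the hypergeometric tail."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_comparison_result
from lfqcarto import (
    ValidationError,
    composite_fdr,
    hgt_pvalue,
    intersect_consistent,
    intersection_significance,
)


def hgt_enumeration(N: int, K: int, n: int, b: int) -> Fraction:
    """Exact tail by summing binomial counts in integer arithmetic."""
    total = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(b, min(K, n) + 1)
        if n - i <= N - K
    )
    return Fraction(total, math.comb(N, n))


class TestHgtPvalue:
    def test_brute_force_draws(self):
        # enumerate all C(10, 5) draws from a 10-element universe with 4 marked
        universe = list(range(10))
        marked = set(range(4))
        hits = [
            len(marked & set(draw)) >= 3 for draw in combinations(universe, 5)
        ]
        assert np.mean(hits) == pytest.approx(11 / 42)
        assert hgt_pvalue(10, 4, 5, 3) == pytest.approx(11 / 42, rel=1e-12)

    def test_tail_from_zero_is_one(self):
        assert hgt_pvalue(50, 7, 12, 0) == 1.0

    def test_impossible_overlap_is_zero(self):
        assert hgt_pvalue(50, 7, 12, min(7, 12) + 1) == 0.0

    def test_matches_enumeration_on_small_grid(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for b in range(min(K, n) + 2):
                        expected = float(hgt_enumeration(N, K, n, b))
                        assert hgt_pvalue(N, K, n, b) == pytest.approx(
                            expected, rel=1e-10, abs=1e-14
                        ), (N, K, n, b)

    def test_monotone_in_overlap_and_marked_count(self):
        N, n = 80, 25
        for K in (5, 20, 60):
            tails = [hgt_pvalue(N, K, n, b) for b in range(min(K, n) + 2)]
            assert all(x >= y for x, y in zip(tails, tails[1:]))
        for b in (0, 3, 7):
            by_k = [hgt_pvalue(N, K, n, b) for K in range(b, N - n + b + 1)]
            assert all(x <= y + 1e-15 for x, y in zip(by_k, by_k[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            hgt_pvalue(10, 11, 5, 2)
        with pytest.raises(ValidationError):
            hgt_pvalue(10, 4, 5, -1)


class TestCompositeFdr:
    def test_expected_equals_observed_gives_one(self):
        assert composite_fdr(100, [(0.1, 1)], 10) == pytest.approx(1.0)

    def test_single_tuple_accepted(self):
        assert composite_fdr(100, (0.1, 1), 10) == pytest.approx(1.0)

    def test_zero_observed_is_undefined(self):
        with pytest.raises(ValidationError):
            composite_fdr(4519, [(0.01, 3)], 0)

    @pytest.mark.parametrize("p", [0.0, 1.0, 1.5])
    def test_threshold_domain(self, p):
        with pytest.raises(ValidationError):
            composite_fdr(100, [(p, 2)], 5)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.integers(1, 10**5),
        st.floats(1e-6, 0.999),
        st.integers(1, 5),
        st.integers(1, 500),
        st.integers(2, 9),
    )
    def test_scales_linearly_in_N_and_inversely_in_m(self, N, p, k, m, factor):
        base = composite_fdr(N, [(p, k)], m)
        assert composite_fdr(N * factor, [(p, k)], m) == pytest.approx(
            base * factor, rel=1e-12
        )
        assert composite_fdr(N, [(p, k)], m * factor) == pytest.approx(
            base / factor, rel=1e-12
        )


class TestIntersectionSignificance:
    def test_uses_two_smallest_counts(self):
        assert intersection_significance([5, 5], 10, 3) == pytest.approx(
            hgt_pvalue(10, 5, 5, 3)
        )
        assert intersection_significance([9, 5, 7], 20, 3) == pytest.approx(
            hgt_pvalue(20, 7, 5, 3)
        )

    def test_zero_intersection_is_one(self):
        assert intersection_significance([50, 60, 70], 1000, 0) == 1.0

    def test_intersection_exceeding_smallest_count_rejected(self):
        with pytest.raises(ValidationError):
            intersection_significance([5, 50], 100, 6)


class TestIntersectConsistent:
    def _three(self, gene_rows):
        return [
            make_comparison_result(f"z{i}_vs_healthy", {g: rows[i] for g, rows in gene_rows.items()})
            for i in range(3)
        ]

    def test_simultaneous_significant_same_sign_called_up(self):
        results = self._three({"G": [(4.0, 0.005), (4.2, 0.008), (3.9, 0.009)],
                               "H": [(1.0, 0.5), (1.0, 0.5), (1.0, 0.5)]})
        called = intersect_consistent(results, 0.01)
        assert called.directions == {"G": "up"}
        assert called.intersection_size == 1

    def test_one_miss_blocks_the_call(self):
        results = self._three({"G": [(4.0, 0.005), (4.2, 0.005), (3.9, 0.02)]})
        assert intersect_consistent(results, 0.01).genes == set()

    def test_sign_flip_blocks_the_call(self):
        results = self._three({"G": [(4.0, 0.005), (4.2, 0.005), (-3.9, 0.005)]})
        assert intersect_consistent(results, 0.01).genes == set()

    def test_down_direction(self):
        results = self._three({"G": [(-4.0, 0.004), (-4.2, 0.008), (-3.9, 0.003)]})
        assert intersect_consistent(results, 0.01).directions == {"G": "down"}

    def test_degenerate_rows_never_qualify(self):
        results = self._three({"G": [(0.0, 0.0, True), (4.0, 0.001), (4.0, 0.001)]})
        assert intersect_consistent(results, 0.01).genes == set()

    def test_counts_pool_both_directions(self):
        results = self._three(
            {
                "G": [(4.0, 0.005), (4.0, 0.005), (4.0, 0.005)],
                "H": [(-4.0, 0.005), (-4.0, 0.5), (4.0, 0.5)],
            }
        )
        called = intersect_consistent(results, 0.01)
        assert called.per_comparison_counts == [2, 1, 1]

    def test_threshold_one_saturates(self, rng):
        genes = {
            f"G{i}": [
                (rng.choice([-1.0, 1.0]) * rng.uniform(0.1, 5), rng.uniform(0.01, 0.99))
                for _ in range(3)
            ]
            for i in range(30)
        }
        called = intersect_consistent(self._three(genes), 1.0)
        expected = {
            g for g, rows in genes.items()
            if len({t > 0 for t, _ in rows}) == 1
        }
        assert called.genes == expected

    def test_mismatched_universes_rejected(self):
        r1 = make_comparison_result("a", {"G": (1.0, 0.5)})
        r2 = make_comparison_result("b", {"H": (1.0, 0.5)})
        with pytest.raises(ValidationError):
            intersect_consistent([r1, r2], 0.05)

    def test_composite_fdr_and_hgt_attached(self):
        results = self._three(
            {
                "G": [(4.0, 0.005), (4.0, 0.005), (4.0, 0.005)],
                "H": [(1.0, 0.9), (1.0, 0.9), (1.0, 0.9)],
            }
        )
        called = intersect_consistent(results, 0.01)
        assert called.composite_fdr == pytest.approx(2 * 0.01**3 / 1)
        assert called.hgt_p == pytest.approx(hgt_pvalue(2, 1, 1, 1))
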