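"""Ranking, the mHG scan, its exact p-value, and gene-set enrichment."""

import itertools

import numpy as np
import pytest

from conftest import make_comparison_result
from lfqcarto import (
    ValidationError,
    enrich_gene_sets,
    mhg_exact_pvalue,
    mhg_scan,
    rank_by_tstat,
)
from lfqcarto.biomarkers import hgt_pvalue
from lfqcarto.io import GeneSet, GeneSetCollection


def enumerate_stats(N: int, B: int) -> np.ndarray:
    """mHG statistic of every arrangement of B ones among N positions."""
    stats = []
    for ones in itertools.combinations(range(N), B):
        v = np.zeros(N, dtype=int)
        v[list(ones)] = 1
        stats.append(mhg_scan(v)[0])
    return np.array(stats)


class TestRanking:
    def _result(self):
        return make_comparison_result(
            "c", {"A": (2.0, 0.1), "B": (-1.0, 0.1), "C": (2.0, 0.1)}
        )

    def test_overexpression_decreasing_t_ties_by_gene(self):
        assert rank_by_tstat(self._result(), "overexpression").genes == ("A", "C", "B")

    def test_underexpression_increasing_t_same_tiebreak(self):
        assert rank_by_tstat(self._result(), "underexpression").genes == ("B", "A", "C")

    def test_degenerate_rows_excluded(self):
        r = make_comparison_result("c", {"A": (2.0, 0.1), "Z": (0.0, 1.0, True)})
        assert rank_by_tstat(r, "overexpression").genes == ("A",)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValidationError):
            rank_by_tstat(self._result(), "sideways")


class TestMhgScan:
    def test_front_loaded_pair(self):
        # prefix tails: HGT(4,2,1,1)=1/2, HGT(4,2,2,2)=1/6, HGT(4,2,3,2)=1/2
        stat, cutoff = mhg_scan([1, 1, 0, 0])
        assert stat == pytest.approx(1 / 6, rel=1e-12)
        assert cutoff == 2

    def test_empty_set_convention(self):
        assert mhg_scan([0, 0, 0, 0]) == (1.0, 1)

    def test_saturated_set_scans_flat(self):
        assert mhg_scan([1, 1, 1, 1]) == (1.0, 1)

    def test_matches_per_prefix_tail_minimum(self, rng):
        for _ in range(30):
            N = int(rng.integers(4, 40))
            B = int(rng.integers(1, N))
            v = np.zeros(N, dtype=int)
            v[rng.choice(N, B, replace=False)] = 1
            stat, cutoff = mhg_scan(v)
            hits = np.cumsum(v)
            tails = [hgt_pvalue(N, B, n, int(hits[n - 1])) for n in range(1, N)]
            assert stat == pytest.approx(min(tails), rel=1e-10)
            assert cutoff == int(np.argmin(tails)) + 1

    def test_non_binary_vector_rejected(self):
        with pytest.raises(ValidationError):
            mhg_scan([0, 2, 1])


class TestMhgExactPvalue:
    def test_unique_extreme_arrangement(self):
        # of the 6 placements of 2 ones in 4 slots only (1,1,0,0) reaches 1/6
        assert mhg_exact_pvalue(1 / 6, 4, 2) == pytest.approx(1 / 6, rel=1e-12)

    def test_stat_of_one_covers_whole_space(self):
        assert mhg_exact_pvalue(1.0, 50, 5) == 1.0

    @pytest.mark.parametrize("N,B", [(8, 3), (9, 4), (10, 2), (11, 5)])
    def test_dp_equals_enumeration(self, N, B):
        stats = enumerate_stats(N, B)
        for s in np.unique(stats):
            expected = np.mean(stats <= s * (1 + 1e-9))
            assert mhg_exact_pvalue(float(s), N, B) == pytest.approx(
                expected, abs=1e-12
            )

    def test_correction_bounds(self, rng):
        # stat <= exact_p <= stat * (N - 1): the minimum is anti-conservative,
        # the union bound over prefixes caps the correction
        for _ in range(40):
            N = int(rng.integers(5, 60))
            B = int(rng.integers(1, N))
            v = np.zeros(N, dtype=int)
            v[rng.choice(N, B, replace=False)] = 1
            stat, _ = mhg_scan(v)
            exact = mhg_exact_pvalue(stat, N, B)
            assert exact >= stat - 1e-12
            assert exact <= stat * (N - 1) + 1e-12

    def test_valid_pvalue_under_random_membership(self, rng):
        # type-I validity of the corrected p-value at alpha = 0.05
        N, B, reps = 200, 10, 2000
        hits = 0
        for _ in range(reps):
            v = np.zeros(N, dtype=int)
            v[rng.choice(N, B, replace=False)] = 1
            stat, _ = mhg_scan(v)
            if mhg_exact_pvalue(stat, N, B) < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 3 * se


class TestEnrichGeneSets:
    def _ranked(self, n=40):
        rows = {f"G{i:02d}": (float(n - i), 0.01) for i in range(n)}
        return rank_by_tstat(make_comparison_result("c", rows), "overexpression")

    def _collection(self, sets):
        return GeneSetCollection(
            sets={
                name: GeneSet(name, "", frozenset(members))
                for name, members in sets.items()
            }
        )

    def test_top_block_is_enriched_and_matches_direct_mhg(self):
        ranked = self._ranked()
        top = {f"G{i:02d}" for i in range(8)}
        results, skipped = enrich_gene_sets(
            ranked, self._collection({"TOP": top}), p_cutoff=1e-3
        )
        assert not skipped
        (res,) = results
        v = [1 if g in top else 0 for g in ranked.genes]
        stat, cutoff = mhg_scan(v)
        assert res.mhg_stat == pytest.approx(stat)
        assert res.cutoff == cutoff == 8
        assert res.exact_p == pytest.approx(mhg_exact_pvalue(stat, 40, 8))
        assert res.significant

    def test_disjoint_set_is_skipped(self):
        results, skipped = enrich_gene_sets(
            self._ranked(), self._collection({"OFF": {"X", "Y"}})
        )
        assert results == [] and skipped == ["OFF"]

    def test_identical_sets_identical_results(self):
        top = {f"G{i:02d}" for i in range(5)}
        results, _ = enrich_gene_sets(
            self._ranked(), self._collection({"S1": top, "S2": set(top)})
        )
        assert len(results) == 2
        a, b = results
        assert (a.mhg_stat, a.cutoff, a.exact_p) == (b.mhg_stat, b.cutoff, b.exact_p)

    def test_members_outside_universe_ignored_in_B(self):
        top = {f"G{i:02d}" for i in range(5)} | {"NOT_THERE"}
        results, _ = enrich_gene_sets(self._ranked(), self._collection({"S": top}))
        assert results[0].B == 5

    def test_empty_universe_rejected(self):
        ranked = rank_by_tstat(
            make_comparison_result("c", {"A": (0.0, 1.0, True)}), "overexpression"
        )
        with pytest.raises(ValidationError):
            enrich_gene_sets(ranked, self._collection({"S": {"A"}}))
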