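"""Within-mouse correlations and unique/shared capture counts."""

import numpy as np
import pandas as pd
import pytest

from lfqcarto import ValidationError, capture_counts, sample_correlations
from lfqcarto.io import IntensityMatrix, SampleAnnotation


def matrix_from(values: dict, annotations: list, genes=None) -> IntensityMatrix:
    n = len(next(iter(values.values())))
    genes = genes or [f"G{i}" for i in range(n)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"))
    m = IntensityMatrix(
        values=df,
        protein_ids=pd.Series([f"P{i}" for i in range(n)], index=df.index),
        extra_genes=pd.Series("", index=df.index),
    )
    return m.attach_annotations(annotations) if annotations else m


def two_sample_matrix(x, y):
    anns = [
        SampleAnnotation("s1", "M1", "tumor", "center", 1, "ebiopsy"),
        SampleAnnotation("s2", "M1", "tumor", "center", 2, "ebiopsy"),
    ]
    return matrix_from({"s1": x, "s2": y}, anns)


class TestSampleCorrelations:
    def test_identical_profiles_correlate_perfectly(self):
        m = two_sample_matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        row = sample_correlations(m).pairs.iloc[0]
        assert row["pearson"] == pytest.approx(1.0)
        assert row["spearman"] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        m = two_sample_matrix([1.0, 2.0, 3.0], [6.0, 5.0, 4.0])
        row = sample_correlations(m).pairs.iloc[0]
        assert row["pearson"] == pytest.approx(-1.0)
        assert row["spearman"] == pytest.approx(-1.0)

    def test_midrank_ties(self):
        # ranks of (1,2,2) and (2,3,3) are both (1, 2.5, 2.5)
        m = two_sample_matrix([1.0, 2.0, 2.0], [2.0, 3.0, 3.0])
        row = sample_correlations(m).pairs.iloc[0]
        assert row["spearman"] == pytest.approx(1.0)

    def test_constant_profile_excluded_from_averages(self):
        anns = [
            SampleAnnotation("s1", "M1", "tumor", "center", 1, "ebiopsy"),
            SampleAnnotation("s2", "M1", "tumor", "center", 2, "ebiopsy"),
            SampleAnnotation("s3", "M1", "tumor", "middle", 1, "ebiopsy"),
        ]
        m = matrix_from(
            {"s1": [1.0, 2.0, 3.0], "s2": [5.0, 5.0, 5.0], "s3": [2.0, 4.0, 6.0]},
            anns,
        )
        report = sample_correlations(m)
        assert report.pairs["pearson"].isna().sum() == 2  # both pairs with s2
        assert report.mouse_averages().loc["M1", "pearson"] == pytest.approx(1.0)

    def test_row_order_invariance_and_monotone_transform(self, rng):
        x = rng.lognormal(size=30)
        y = x * rng.lognormal(0, 0.1, size=30)
        base = sample_correlations(two_sample_matrix(x, y)).pairs.iloc[0]
        perm = rng.permutation(30)
        shuffled = sample_correlations(two_sample_matrix(x[perm], y[perm])).pairs.iloc[0]
        assert base["pearson"] == pytest.approx(shuffled["pearson"])
        assert base["spearman"] == pytest.approx(shuffled["spearman"])
        cubed = sample_correlations(two_sample_matrix(x, y**3)).pairs.iloc[0]
        assert cubed["spearman"] == pytest.approx(base["spearman"])

    def test_correlations_computed_per_mouse(self, small_study):
        _, matrix, _ = small_study
        report = sample_correlations(matrix)
        assert set(report.pairs["mouse_id"]) == {f"M{i}" for i in range(1, 6)}
        # 7 samples per mouse -> 21 unordered pairs each
        assert (report.pairs.groupby("mouse_id").size() == 21).all()
        mat = report.matrix("M1")
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T)

    def test_replica_correlation_exceeds_cross_tissue(self, small_study):
        _, matrix, _ = small_study
        pairs = sample_correlations(matrix).pairs
        is_replica = pairs.apply(
            lambda r: r["sample_i"].rsplit("_", 1)[0] == r["sample_j"].rsplit("_", 1)[0],
            axis=1,
        )
        healthy = pairs.apply(
            lambda r: "healthy" in r["sample_i"] or "healthy" in r["sample_j"], axis=1
        )
        assert (
            pairs[is_replica]["pearson"].mean()
            > pairs[healthy]["pearson"].mean()
        )


class TestCaptureCounts:
    def test_per_protein_partition(self):
        a = matrix_from(
            {"s": [1.0, 0.0, 5.0]},
            [SampleAnnotation("s", "M1", "tumor", "center", 1, "ebiopsy")],
        )
        b = matrix_from(
            {"s": [0.0, 2.0, 3.0]},
            [SampleAnnotation("s", "M1", "tumor", "center", 1, "lysis")],
        )
        counts = capture_counts(a, b, scope="per_sample")
        assert (counts.unique_a, counts.unique_b, counts.both) == (1, 1, 1)
        assert counts.universe == 3

    def test_identical_matrices_share_everything(self, small_study):
        _, matrix, _ = small_study
        counts = capture_counts(matrix, matrix)
        assert counts.unique_a == counts.unique_b == 0
        assert counts.universe == matrix.n_proteins

    def test_pooled_scope_counts_any_positive_sample(self):
        anns = [
            SampleAnnotation("r1", "M1", "tumor", "center", 1, "ebiopsy"),
            SampleAnnotation("r2", "M1", "tumor", "center", 2, "ebiopsy"),
        ]
        a = matrix_from({"r1": [0.0], "r2": [3.0]}, anns, genes=["G"])
        b = matrix_from(
            {"s": [0.0]},
            [SampleAnnotation("s", "M1", "tumor", "center", 1, "lysis")],
            genes=["G"],
        )
        counts = capture_counts(a, b, scope="pooled")
        assert counts.unique_a == 1  # present in replica 2 only still counts

    def test_universe_mismatch_rejected(self):
        a = matrix_from(
            {"s": [1.0]},
            [SampleAnnotation("s", "M1", "tumor", "center", 1, "ebiopsy")],
            genes=["G1"],
        )
        b = matrix_from(
            {"s": [1.0]},
            [SampleAnnotation("s", "M1", "tumor", "center", 1, "lysis")],
            genes=["G2"],
        )
        with pytest.raises(ValidationError):
            capture_counts(a, b)
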