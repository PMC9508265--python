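"""Reproducibility and capture diagnostics.

Inter-sample correlations are computed within each mouse (every pair of
that mouse's samples), as Pearson on the raw LFQ profiles and Spearman on
mid-ranks, then averaged per mouse and across mice.  Zeros are ordinary
profile values by default — the full vectors are correlated; a flag
restricts pairs to proteins detected in both samples.

Capture counts compare two matrices (e.g. two extraction methods) over a
shared protein universe: a protein exists in a sample when its intensity
is strictly positive (pooled scope: positive in any sample of the group);
proteins are then uniquely captured by one side, by the other, or by both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntensityMatrix, ValidationError

__all__ = [
    "CorrelationReport",
    "CaptureCounts",
    "sample_correlations",
    "capture_counts",
]


@dataclass
class CorrelationReport:
    """Pairwise within-mouse sample correlations.

    ``pairs`` has one row per unordered sample pair per mouse with
    ``pearson``/``spearman`` columns (NaN when a profile is constant and
    the coefficient is undefined; such pairs are excluded from averages).
    """

    pairs: pd.DataFrame

    def mouse_averages(self) -> pd.DataFrame:
        return self.pairs.groupby("mouse_id")[["pearson", "spearman"]].mean()

    def grand_average(self) -> pd.Series:
        # average of per-mouse averages, so mice weigh equally
        return self.mouse_averages().mean()

    def matrix(self, mouse_id: str, kind: str = "pearson") -> pd.DataFrame:
        sub = self.pairs[self.pairs["mouse_id"] == mouse_id]
        names = sorted(set(sub["sample_i"]) | set(sub["sample_j"]))
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for _, row in sub.iterrows():
            mat.loc[row["sample_i"], row["sample_j"]] = row[kind]
            mat.loc[row["sample_j"], row["sample_i"]] = row[kind]
        return mat


def sample_correlations(
    matrix: IntensityMatrix, nonzero_only: bool = False
) -> CorrelationReport:
    """Pearson and Spearman correlations between samples of each mouse.

    ``nonzero_only=True`` restricts each pair to proteins with positive
    intensity in both samples before correlating.
    """
    ann = matrix.require_annotations()
    rows = []
    for mouse, group in ann.groupby("mouse_id"):
        samples = list(group.index)
        if len(samples) < 2:
            raise ValidationError(f"mouse {mouse!r} has fewer than 2 samples")
        for s_i, s_j in combinations(samples, 2):
            x = matrix.values[s_i].to_numpy(dtype=float)
            y = matrix.values[s_j].to_numpy(dtype=float)
            if nonzero_only:
                keep = (x > 0) & (y > 0)
                x, y = x[keep], y[keep]
            if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
                pear = spear = np.nan  # undefined for constant profiles
            else:
                pear = stats.pearsonr(x, y).statistic
                spear = stats.spearmanr(x, y).statistic
            rows.append(
                {
                    "mouse_id": mouse,
                    "sample_i": s_i,
                    "sample_j": s_j,
                    "pearson": pear,
                    "spearman": spear,
                }
            )
    return CorrelationReport(pairs=pd.DataFrame(rows))


@dataclass
class CaptureCounts:
    unique_a: int
    unique_b: int
    both: int
    neither: int

    @property
    def universe(self) -> int:
        return self.unique_a + self.unique_b + self.both + self.neither


def capture_counts(
    matrix_a: IntensityMatrix,
    matrix_b: IntensityMatrix,
    scope: str = "pooled",
) -> CaptureCounts:
    """Unique/shared protein capture between two matrices.

    A protein exists on a side when its intensity is strictly positive in
    any of that side's samples.  ``scope="pooled"`` accepts arbitrary
    groups on each side (e.g. all samples of a location);
    ``scope="per_sample"`` is the single-sample comparison and requires
    both sides to have equally many columns (typically one each).
    """
    if not matrix_a.genes.equals(matrix_b.genes):
        raise ValidationError("capture comparison needs a shared protein universe")
    va = matrix_a.values.to_numpy(dtype=float)
    vb = matrix_b.values.to_numpy(dtype=float)
    if scope == "per_sample":
        if va.shape[1] != vb.shape[1]:
            raise ValidationError("per-sample scope needs equally many samples")
    elif scope != "pooled":
        raise ValidationError(f"unknown scope {scope!r}")
    in_a = (va > 0).any(axis=1)
    in_b = (vb > 0).any(axis=1)
    return CaptureCounts(
        unique_a=int((in_a & ~in_b).sum()),
        unique_b=int((~in_a & in_b).sum()),
        both=int((in_a & in_b).sum()),
        neither=int((~in_a & ~in_b).sum()),
    )
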