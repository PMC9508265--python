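"""Per-protein paired differential testing and geometric-mean fold change.

The test is the plain two-sided paired Student t-test on raw LFQ values
(no log transform by default, matching how the vectors are built upstream;
a log2 option exists behind a flag).  Fold change is the geometric mean of
the per-pair a/b ratios after replacing zeros with the dataset floor.

A protein whose paired differences have zero sample variance cannot be
t-tested; such rows are flagged ``degenerate`` and by convention carry
t = 0 with p = 1 when the vectors are identical, p = 0 when they differ
by a constant shift.  Degenerate rows stay in output tables but are
excluded from downstream ranking and intersection counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .preprocess import PairedContrast

__all__ = [
    "TTestResult",
    "ComparisonResult",
    "paired_ttest",
    "geometric_fold_change",
    "compare_groups",
]


class TTestResult(NamedTuple):
    t_stat: float
    p_value: float
    df: int
    degenerate: bool


def paired_ttest(a, b) -> TTestResult:
    """Two-sided paired Student t-test on one pair of aligned vectors.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and sample sd (n-1
    denominator); p is the two-sided tail of Student's t with n-1 degrees
    of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValidationError("paired t-test needs n >= 2")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, df, True)
        return TTestResult(0.0, 0.0, df, True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), df, False)


def geometric_fold_change(a, b, floor: float) -> float:
    """Geometric mean of per-pair a/b ratios with zeros floored.

    Zeros in either vector are replaced by ``floor`` (half the minimal
    positive intensity of the dataset) before forming ratios, so the
    result is always finite and positive.
    """
    if floor <= 0:
        raise ValidationError("floor must be strictly positive")
    a = np.where(np.asarray(a, dtype=float) == 0.0, floor, a)
    b = np.where(np.asarray(b, dtype=float) == 0.0, floor, b)
    return float(np.exp(np.mean(np.log(a / b))))


@dataclass
class ComparisonResult:
    """Per-protein output of one paired contrast.

    ``table`` is indexed by gene with columns ``t_stat``, ``p_value``,
    ``fold_change``, ``n_pairs``, ``degenerate``.  The protein universe of
    the contrast is the full index, degenerate rows included; callers that
    rank or intersect use :meth:`nondegenerate`.
    """

    contrast: str
    table: pd.DataFrame

    @property
    def universe(self) -> pd.Index:
        return self.table.index

    @property
    def n_proteins(self) -> int:
        return len(self.table)

    def nondegenerate(self) -> pd.DataFrame:
        return self.table[~self.table["degenerate"]]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out.insert(0, "contrast", self.contrast)
        return out


def compare_groups(
    contrast: PairedContrast, floor: float, log_scale: bool = False
) -> ComparisonResult:
    """Apply the paired t-test and geometric fold change to every protein.

    ``log_scale=True`` runs the t-test on log2 intensities (zeros floored
    first); the default tests raw values.  No multiple-testing adjustment
    happens here — the composite FDR is a downstream closed form.
    """
    a = contrast.a_values
    b = contrast.b_values
    n = contrast.n_pairs
    if floor <= 0:
        raise ValidationError("floor must be strictly positive")

    a_floored = np.where(a == 0.0, floor, a)
    b_floored = np.where(b == 0.0, floor, b)
    if log_scale:
        d = np.log2(a_floored) - np.log2(b_floored)
    else:
        d = a - b
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, mean / (sd / np.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    # degenerate conventions: identical vectors p=1, constant shift p=0
    p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0), p)

    fold = np.exp(np.mean(np.log(a_floored / b_floored), axis=1))

    table = pd.DataFrame(
        {
            "t_stat": t,
            "p_value": p,
            "fold_change": fold,
            "n_pairs": n,
            "degenerate": degenerate,
        },
        index=contrast.genes,
    )
    return ComparisonResult(contrast=contrast.name, table=table)
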