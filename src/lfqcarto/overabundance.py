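"""Observed-vs-expected p-value distribution diagnostics.

For a batch of N per-protein p-values, the overabundance curve records,
at every distinct observed p-value t, the observed count of tests with
p <= t against the N * t expected under the uniform null of independent
tests.  Observed counts far above the diagonal indicate genuine signal;
a null dataset stays inside the binomial confidence band of the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "OverabundanceCurve",
    "overabundance_curve",
    "within_null_band",
    "plot_overabundance",
]


@dataclass
class OverabundanceCurve:
    """Cumulative observed vs expected significance counts.

    ``max_enrichment`` is the largest observed/expected ratio over
    thresholds with expected count >= 1 (tiny thresholds are excluded
    because the ratio there is dominated by discreteness).
    """

    thresholds: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    n_tests: int

    @property
    def max_enrichment(self) -> float:
        mask = self.expected >= 1.0
        if not mask.any():
            return float("nan")
        return float(np.max(self.observed[mask] / self.expected[mask]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed": self.observed.astype(int),
                "expected": self.expected,
            }
        )


def overabundance_curve(p_values) -> OverabundanceCurve:
    """Build the curve from a batch of p-values (degenerates excluded upstream)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        empty = np.array([])
        return OverabundanceCurve(empty, empty, empty, 0)
    thresholds, counts = np.unique(p, return_counts=True)
    observed = np.cumsum(counts).astype(float)
    expected = p.size * thresholds
    return OverabundanceCurve(thresholds, observed, expected, int(p.size))


def within_null_band(
    curve: OverabundanceCurve, n_se: float = 3.0, min_expected: float = 10.0
) -> bool:
    """Whether the curve stays inside the +-n_se binomial band of the diagonal.

    Under the uniform null, observed(t) ~ Binomial(N, t) with mean N*t and
    SE sqrt(N*t*(1-t)).  The band is only meaningful where the normal
    approximation holds, so thresholds with expected < ``min_expected``
    are not checked.
    """
    mask = curve.expected >= min_expected
    if not mask.any():
        return True
    t = curve.thresholds[mask]
    se = np.sqrt(curve.n_tests * t * (1 - t))
    dev = np.abs(curve.observed[mask] - curve.expected[mask])
    return bool(np.all(dev <= n_se * se + 1e-9))


def plot_overabundance(
    curve: OverabundanceCurve, path: str | Path, title: str = "", log: bool = True
) -> None:
    """Optional plot layer (matplotlib): observed vs expected with diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve.expected, curve.observed, lw=1.5, label="observed")
    lim = max(curve.n_tests, 1)
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="uniform null")
    if log:
        ax.set_xscale("symlog")
        ax.set_yscale("symlog")
    ax.set_xlabel("expected count (N · t)")
    ax.set_ylabel("observed count (p ≤ t)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
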