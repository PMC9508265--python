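"""Tumor-vs-healthy biomarker calling by multi-zone intersection.

A gene is called a biomarker when its paired test is significant — with a
consistent sign — in every zone-vs-healthy contrast simultaneously.  Two
significance summaries accompany the intersection:

* the composite FDR, the closed-form ratio of intersections expected by
  chance to intersections observed, N * prod(p_i ** k_i) / m, where N is
  the protein universe, each threshold p_i was applied in k_i simultaneous
  tests, and m is the observed intersection size; and
* a hypergeometric-tail (HGT) upper bound on the probability of seeing an
  intersection that large, computed from the two smallest per-contrast
  significant-gene counts.

The HGT is evaluated exactly in log space (log-gamma binomial terms summed
with log-sum-exp), so desk-scale parameters never underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .diffexpr import ComparisonResult
from .io import ValidationError

__all__ = [
    "BiomarkerSet",
    "hgt_pvalue",
    "composite_fdr",
    "intersect_consistent",
    "intersection_significance",
]


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------

def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hgt_pvalue(N: int, K: int, n: int, b: int) -> float:
    """Exact upper tail P(X >= b) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the marked elements, n the draws, b the
    observed overlap.  Computed by summing exact log-pmf terms with
    log-sum-exp, so small tails stay accurate.
    """
    N, K, n, b = int(N), int(K), int(n), int(b)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid HGT parameters N={N}, K={K}, n={n}")
    if b < 0:
        raise ValidationError(f"overlap b={b} must be >= 0")
    upper = min(K, n)
    lowest_possible = max(0, n - (N - K))
    if b > upper:
        return 0.0
    if b <= lowest_possible:
        return 1.0
    i = np.arange(b, upper + 1)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def intersection_significance(
    per_comparison_counts: Sequence[int], N: int, intersection_size: int
) -> float:
    """HGT upper bound on a k-way intersection being as large as observed.

    With k >= 2 per-contrast significant-gene counts, the two smallest
    act as the marked set K and the draw size n of a two-set overlap; the
    two-set tail bounds the k-way intersection probability from above
    (every additional contrast only shrinks the intersection).
    """
    counts = sorted(int(c) for c in per_comparison_counts)
    if len(counts) < 2:
        raise ValidationError("need >= 2 per-comparison counts")
    if intersection_size > counts[0]:
        raise ValidationError(
            f"intersection ({intersection_size}) exceeds the smallest "
            f"per-comparison count ({counts[0]})"
        )
    n_draws, K = counts[0], counts[1]
    return hgt_pvalue(N, K, n_draws, intersection_size)


# ---------------------------------------------------------------------------
# Composite FDR
# ---------------------------------------------------------------------------

def composite_fdr(
    N: int,
    threshold_powers: Sequence[tuple] | tuple,
    m: int,
) -> float:
    """Expected chance intersections over observed: N * prod(p**k) / m.

    ``threshold_powers`` is a list of (p, k) pairs — each per-test
    threshold p applied in k simultaneous comparisons; a single (p, k)
    tuple is accepted too.  The value is returned uncapped (it is a ratio,
    not a probability); display layers may cap at 1.
    """
    if m < 1:
        raise ValidationError("composite FDR undefined for m = 0")
    if N < 1:
        raise ValidationError("universe size N must be >= 1")
    if threshold_powers and not isinstance(threshold_powers[0], (tuple, list)):
        threshold_powers = [tuple(threshold_powers)]
    chance = float(N)
    for p, k in threshold_powers:
        if not 0 < p < 1:
            raise ValidationError(f"threshold p={p} must be in (0, 1)")
        if int(k) < 1:
            raise ValidationError(f"exponent k={k} must be >= 1")
        chance *= float(p) ** int(k)
    return chance / m


# ---------------------------------------------------------------------------
# Intersection calling
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSet:
    """Genes significant with one sign in every contrast simultaneously."""

    directions: dict = field(default_factory=dict)  # gene -> "up" | "down"
    p_threshold: float = 0.01
    k_comparisons: int = 0
    per_comparison_counts: list = field(default_factory=list)
    universe_size: int = 0
    composite_fdr: float | None = None  # None when the intersection is empty
    hgt_p: float = 1.0

    @property
    def genes(self) -> set:
        return set(self.directions)

    @property
    def intersection_size(self) -> int:
        return len(self.directions)

    def genes_with_direction(self, direction: str) -> set:
        return {g for g, d in self.directions.items() if d == direction}


def intersect_consistent(
    results: Sequence[ComparisonResult], p_threshold: float
) -> BiomarkerSet:
    """Call genes significant with consistent direction in every contrast.

    All contrasts must share the same protein universe and the same
    reference side (so a positive t means the same direction in each).
    A gene is called up iff p < p_threshold and t > 0 everywhere, down
    iff p < p_threshold and t < 0 everywhere; degenerate rows never
    qualify.  ``per_comparison_counts`` record each contrast's total
    significant-gene count pooling both directions, as used by the HGT
    bound.
    """
    if len(results) < 2:
        raise ValidationError("intersection needs >= 2 contrasts")
    if not 0 < p_threshold <= 1:
        raise ValidationError(f"p_threshold={p_threshold} must be in (0, 1]")
    universe = results[0].universe
    for r in results[1:]:
        if not r.universe.equals(universe):
            raise ValidationError(
                f"contrast {r.contrast!r} has a different protein universe"
            )
    N = len(universe)

    sig = []
    up = []
    down = []
    for r in results:
        t = r.table["t_stat"].to_numpy()
        p = r.table["p_value"].to_numpy()
        ok = (~r.table["degenerate"].to_numpy()) & (p < p_threshold)
        sig.append(ok)
        up.append(ok & (t > 0))
        down.append(ok & (t < 0))
    counts = [int(s.sum()) for s in sig]
    all_up = np.logical_and.reduce(up)
    all_down = np.logical_and.reduce(down)

    directions = {g: "up" for g in universe[all_up]}
    directions.update({g: "down" for g in universe[all_down]})

    m = len(directions)
    if m == 0:
        fdr = None
    elif p_threshold == 1.0:  # saturated calling: every gene expected by chance
        fdr = N / m
    else:
        fdr = composite_fdr(N, [(p_threshold, len(results))], m)
    hgt = intersection_significance(counts, N, m)
    return BiomarkerSet(
        directions=directions,
        p_threshold=p_threshold,
        k_comparisons=len(results),
        per_comparison_counts=counts,
        universe_size=N,
        composite_fdr=fdr,
        hgt_p=hgt,
    )
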