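"""Ranked gene-set enrichment by the minimum-hypergeometric (mHG) statistic.

Genes are ranked by their paired-test t statistic (decreasing for
overexpression, increasing for underexpression; ties broken by gene id so
the order is a deterministic total order).  For a gene set occupying B of
the N ranked positions, the mHG statistic is the minimum over every
prefix length n in 1..N-1 of the hypergeometric tail
HGT(N, B, n, b_n), where b_n counts set members in the first n positions.

Because the cutoff is optimized, the raw minimum is anti-conservative;
the exact p-value is the probability, over the C(N, B) equally likely
placements of the B members, that the minimum is at least as small.  It
is computed by dynamic programming over the (prefix, hits) lattice:
paths walk the lattice with hypergeometric step probabilities, mass
entering the rejection region {(n, b): HGT(N, B, n, b) <= stat} is
absorbed, and the absorbed total is the p-value.  All quantities are
probabilities in [0, 1], so plain double precision is stable; the region
boundary uses the same tail routine as the scan plus a relative epsilon
(1e-9) so that tails equal to the statistic up to float rounding fall
inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import _log_binom
from .diffexpr import ComparisonResult
from .io import GeneSetCollection, ValidationError

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_by_tstat",
    "mhg_scan",
    "mhg_exact_pvalue",
    "enrich_gene_sets",
]

DIRECTIONS = ("overexpression", "underexpression")

#: relative slack when testing a hypergeometric tail against the observed
#: statistic; absorbs float rounding between equal-valued tails
REJECTION_EPS = 1e-9


@dataclass(frozen=True)
class RankedList:
    """A deterministic total order of genes by t statistic."""

    genes: tuple
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_tstat(result: ComparisonResult, direction: str) -> RankedList:
    """Rank the non-degenerate genes of a contrast by t statistic.

    ``overexpression`` sorts by decreasing t, ``underexpression`` by
    increasing t; ties broken lexicographically by gene id either way.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"unknown direction {direction!r}")
    tab = result.nondegenerate()
    key = -tab["t_stat"] if direction == "overexpression" else tab["t_stat"]
    order = (
        pd.DataFrame({"key": key.to_numpy(), "gene": tab.index})
        .sort_values(["key", "gene"], kind="mergesort")
    )
    return RankedList(genes=tuple(order["gene"]), direction=direction)


def _tail_table(N: int, B: int) -> np.ndarray:
    """(N+1) x (B+1) table of upper tails P(X >= b) for X ~ HG(N, B, n).

    Row n holds the tail as a function of the hit count b after n draws;
    infeasible cells (b > min(B, n)) are 0, cells at or below the least
    possible hit count are 1.  Both the scan and the exact-p rejection
    boundary read this one table, so their tail values are bit-identical.
    """
    n = np.arange(N + 1)[:, None]
    i = np.arange(B + 1)[None, :]
    with np.errstate(invalid="ignore"):
        logpmf = _log_binom(B, i) + _log_binom(N - B, n - i) - _log_binom(N, n)
    feasible = (i <= np.minimum(B, n)) & (n - i <= N - B)
    logpmf = np.where(feasible, logpmf, -np.inf)
    # accumulate the tail right-to-left in log space
    logtail = np.logaddexp.accumulate(logpmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(np.exp(logtail), 1.0)


def mhg_scan(membership) -> tuple[float, int]:
    """Minimum hypergeometric tail over all proper prefixes.

    ``membership`` is the binary indicator of set membership down the
    ranked list.  Returns (statistic, cutoff) where the cutoff is the
    smallest prefix length achieving the minimum.  An empty (B = 0) or
    saturated (B = N) set scans flat and returns (1.0, 1).
    """
    v = np.asarray(list(membership), dtype=int)
    if v.ndim != 1 or ((v != 0) & (v != 1)).any():
        raise ValidationError("membership must be a binary vector")
    N = v.size
    if N < 2:
        raise ValidationError("ranked universe must have >= 2 genes")
    B = int(v.sum())
    if B == 0:
        return 1.0, 1
    tails = _tail_table(N, B)
    hits = np.cumsum(v)
    prefix_tails = tails[np.arange(1, N), hits[: N - 1]]
    cutoff = int(np.argmin(prefix_tails)) + 1  # argmin takes the first minimum
    best = float(prefix_tails[cutoff - 1])
    if best >= 1.0:
        return 1.0, 1
    return best, cutoff


def _rejection_boundary(stat: float, N: int, B: int) -> np.ndarray:
    """Smallest hit count b with HGT(N, B, n, b) <= stat, per prefix n.

    Entry n (prefixes 1..N-1) is B + 1 when no hit count enters the
    rejection region at that prefix.  Reads the same tail table as the
    scan, with REJECTION_EPS relative slack so tails equal to the
    statistic up to float rounding fall inside the region.
    """
    limit = stat * (1.0 + REJECTION_EPS)
    tails = _tail_table(N, B)
    # tails are non-increasing in b, so the region is a suffix of each row
    inside = tails <= limit
    boundary = (B + 1) - inside.sum(axis=1)
    boundary[0] = B + 1  # prefix 0 is not scanned
    if N >= 1:
        boundary[-1] = B + 1  # the full list is not a proper prefix
    return boundary


def mhg_exact_pvalue(stat: float, N: int, B: int) -> float:
    """Exact p-value of an observed mHG statistic.

    Probability that a uniformly random placement of B ones among N
    positions yields an mHG statistic <= ``stat``.
    """
    N, B = int(N), int(B)
    if not 0 <= B <= N:
        raise ValidationError(f"need 0 <= B <= N, got B={B}, N={N}")
    if stat >= 1.0:
        return 1.0
    if B == 0 or B == N or N < 2:
        # the scan is identically 1, which is never <= stat < 1
        return 0.0
    boundary = _rejection_boundary(stat, N, B)

    # w[b] = P(path reaches (n, b) without having entered the region)
    w = np.zeros(B + 1)
    w[0] = 1.0
    rejected = 0.0
    for n in range(1, N + 1):
        b = np.arange(B + 1)
        remaining = N - (n - 1)
        p_one = (B - b) / remaining  # chance the next gene is a member
        w_new = np.zeros(B + 1)
        w_new += w * (1.0 - p_one)
        w_new[1:] += (w * p_one)[:-1]
        if n <= N - 1:
            cut = boundary[n]
            if cut <= B:
                rejected += w_new[cut:].sum()
                w_new[cut:] = 0.0
        w = w_new
    return float(min(1.0, rejected))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    N: int
    B: int
    mhg_stat: float
    cutoff: int
    exact_p: float
    significant: bool


def enrich_gene_sets(
    ranked: RankedList,
    sets: GeneSetCollection,
    p_cutoff: float = 1e-6,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Test every gene set for overabundance at the top of the ranking.

    Sets are first intersected with the ranked universe; sets left empty
    are skipped and reported in the second return value.  Results are
    sorted by exact p-value (ties by set name) and flagged significant at
    ``p_cutoff``.
    """
    if len(ranked) == 0:
        raise ValidationError("empty ranked universe")
    index = {g: i for i, g in enumerate(ranked.genes)}
    N = len(ranked)
    results = []
    skipped = []
    for gs in sets:
        positions = [index[g] for g in gs.members if g in index]
        if not positions:
            skipped.append(gs.name)
            continue
        membership = np.zeros(N, dtype=int)
        membership[positions] = 1
        stat, cutoff = mhg_scan(membership)
        exact = mhg_exact_pvalue(stat, N, len(positions))
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                N=N,
                B=len(positions),
                mhg_stat=stat,
                cutoff=cutoff,
                exact_p=exact,
                significant=exact < p_cutoff,
            )
        )
    results.sort(key=lambda r: (r.exact_p, r.set_name))
    return results, skipped
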