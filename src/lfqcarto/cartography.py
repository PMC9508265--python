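"""Intratumor heterogeneity: zone-specific calls and the cartography map.

A gene is specific to a zone when both pairwise contrasts involving that
zone are significant with the sign pointing the same way — e.g. up in the
center means center > middle and center > periphery, each at
p < p_threshold; the third contrast (middle vs periphery) is not relevant
for a center call.  Down-calls mirror this.

Zone-specific genes are then intersected with the potential-biomarker set
(the looser tumor-vs-healthy intersection) to give the map of
heterogeneously expressed biomarkers.  Membership alone decides the
intersection: a zone call does not have to share the tumor-vs-healthy
direction (a tumor-overexpressed gene may still be the low zone of the
tumor).  Each zone's combined FDR stacks both criteria:
N * p_zone**2 * p_marker**3 / m.

The full table may place one gene in two cells (up in one zone and down
in another is geometrically consistent); the "unique" map keeps only each
gene's strongest assignment (smallest max-p over its two defining
contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .biomarkers import composite_fdr
from .diffexpr import ComparisonResult
from .io import ValidationError

__all__ = ["ZoneCalls", "CartographyMap", "zone_specific_calls", "build_cartography"]

ZONES = ("center", "middle", "periphery")
DIRECTIONS = ("up", "down")

#: contrast name -> (a side, b side); positive t means a > b
_REQUIRED_CONTRASTS = {
    "center_vs_middle": ("center", "middle"),
    "center_vs_periphery": ("center", "periphery"),
    "middle_vs_periphery": ("middle", "periphery"),
}


@dataclass
class ZoneCalls:
    """Per-(zone, direction) gene calls before biomarker filtering.

    ``cells`` maps (zone, direction) -> {gene: max p over the two
    defining contrasts}; the max-p doubles as the strength key for the
    unique map.
    """

    cells: dict = field(default_factory=dict)
    p_threshold: float = 0.05
    universe_size: int = 0

    def genes(self, zone: str, direction: str) -> set:
        return set(self.cells.get((zone, direction), {}))

    @property
    def zone_counts(self) -> dict:
        return {
            z: (len(self.genes(z, "up")), len(self.genes(z, "down"))) for z in ZONES
        }


def zone_specific_calls(
    results: Mapping[str, ComparisonResult], p_threshold: float
) -> ZoneCalls:
    """Call genes differential in a single zone against both others.

    ``results`` must contain the three pairwise zone contrasts under their
    canonical names (``center_vs_middle`` etc., a-side listed first).
    """
    missing = [k for k in _REQUIRED_CONTRASTS if k not in results]
    if missing:
        raise ValidationError(f"missing zone contrasts: {missing}")
    if not 0 < p_threshold <= 1:
        raise ValidationError(f"p_threshold={p_threshold} must be in (0, 1]")
    universe = results["center_vs_middle"].universe
    for name in _REQUIRED_CONTRASTS:
        if not results[name].universe.equals(universe):
            raise ValidationError(f"contrast {name!r} has a different universe")

    def signed(name: str, want_a_greater: bool):
        """significance mask + p for 'the zone side exceeds the other'."""
        tab = results[name].table
        t = tab["t_stat"].to_numpy()
        p = tab["p_value"].to_numpy()
        ok = (~tab["degenerate"].to_numpy()) & (p < p_threshold)
        ok &= (t > 0) if want_a_greater else (t < 0)
        return ok, p

    # which two contrasts define each zone, and on which side the zone sits
    zone_rules = {
        "center": (("center_vs_middle", True), ("center_vs_periphery", True)),
        "middle": (("center_vs_middle", False), ("middle_vs_periphery", True)),
        "periphery": (("center_vs_periphery", False), ("middle_vs_periphery", False)),
    }

    cells: dict = {}
    for zone, rules in zone_rules.items():
        for direction in DIRECTIONS:
            greater = direction == "up"
            (n1, s1), (n2, s2) = rules
            ok1, p1 = signed(n1, s1 if greater else not s1)
            ok2, p2 = signed(n2, s2 if greater else not s2)
            mask = ok1 & ok2
            max_p = np.maximum(p1, p2)
            cells[(zone, direction)] = {
                g: float(mp) for g, mp in zip(universe[mask], max_p[mask])
            }
    return ZoneCalls(cells=cells, p_threshold=p_threshold, universe_size=len(universe))


@dataclass
class CartographyMap:
    """The zone x direction map of heterogeneously expressed biomarkers.

    ``table_cells`` keeps every qualifying (zone, direction, gene)
    assignment; ``map_cells`` is the single-zone map where each gene
    appears once, in its strongest cell.  Empty cells are represented by
    empty tuples and rendered as ``NULL``.  ``combined_fdr`` per zone is
    ``None`` where no gene survived.
    """

    table_cells: dict = field(default_factory=dict)
    map_cells: dict = field(default_factory=dict)
    zone_counts: dict = field(default_factory=dict)
    combined_fdr: dict = field(default_factory=dict)
    p_zone: float = 0.05
    p_marker: float = 0.05
    universe_size: int = 0

    def to_map_frame(self) -> pd.DataFrame:
        rows = []
        for zone in ZONES:
            for direction in DIRECTIONS:
                genes = self.map_cells.get((zone, direction), ())
                rows.append(
                    {
                        "zone": zone,
                        "direction": direction,
                        "genes": ";".join(genes) if genes else "NULL",
                    }
                )
        return pd.DataFrame(rows)


def build_cartography(
    zone_calls: ZoneCalls,
    biomarker_genes: set,
    N: int,
    p_zone: float = 0.05,
    p_marker: float = 0.05,
) -> CartographyMap:
    """Intersect zone-specific calls with the potential-biomarker set.

    ``N`` is the protein universe size; the combined FDR per zone is
    N * p_zone**2 * p_marker**3 / m over the m intersected genes of that
    zone (both directions pooled), ``None`` when m = 0.
    """
    biomarker_genes = set(biomarker_genes)
    table_cells: dict = {}
    strength: dict = {}  # gene -> (max_p, zone, direction)
    for (zone, direction), genes_p in zone_calls.cells.items():
        kept = {g: p for g, p in genes_p.items() if g in biomarker_genes}
        table_cells[(zone, direction)] = tuple(sorted(kept))
        for g, p in kept.items():
            if g not in strength or p < strength[g][0]:
                strength[g] = (p, zone, direction)

    map_cells = {key: [] for key in table_cells}
    for g, (_, zone, direction) in strength.items():
        map_cells[(zone, direction)].append(g)
    map_cells = {k: tuple(sorted(v)) for k, v in map_cells.items()}

    zone_counts = {
        z: (
            len(table_cells.get((z, "up"), ())),
            len(table_cells.get((z, "down"), ())),
        )
        for z in ZONES
    }
    combined = {}
    for z, (n_up, n_down) in zone_counts.items():
        m = n_up + n_down
        combined[z] = (
            composite_fdr(N, [(p_zone, 2), (p_marker, 3)], m) if m else None
        )
    return CartographyMap(
        table_cells=table_cells,
        map_cells=map_cells,
        zone_counts=zone_counts,
        combined_fdr=combined,
        p_zone=p_zone,
        p_marker=p_marker,
        universe_size=N,
    )
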