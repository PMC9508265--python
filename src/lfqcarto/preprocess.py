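"""Turn an annotated intensity matrix into contrast-ready paired vectors.

Two paired designs are supported, mirroring how the study compares groups:

* tumor zone vs healthy breast — the two technical replicas of a zone are
  averaged first, then each mouse's zone mean is paired with that mouse's
  healthy sample (n = number of mice);
* zone vs zone within the tumor — replica r of zone A is paired with
  replica r of zone B in the same mouse (n = mice x replicas), keeping
  both replicas as separate paired observations.

Zeros (dropout) are ordinary numeric values throughout averaging and
testing; the global floor exists only for fold-change ratios downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IntensityMatrix, SampleAnnotation, ValidationError

__all__ = [
    "PairedContrast",
    "average_replicas",
    "global_floor",
    "build_contrast",
    "tumor_vs_healthy_contrasts",
    "zone_pair_contrasts",
    "ZONE_PAIRS",
]

#: canonical orientation of the three pairwise zone contrasts
ZONE_PAIRS = (
    ("center", "middle"),
    ("center", "periphery"),
    ("middle", "periphery"),
)


@dataclass
class PairedContrast:
    """Aligned per-protein paired vectors for one comparison.

    ``a_values`` and ``b_values`` are (proteins x pairs) arrays aligned
    index-by-index on ``pair_keys``; positive downstream t statistics mean
    a > b.
    """

    name: str
    genes: pd.Index
    a_values: np.ndarray
    b_values: np.ndarray
    pair_keys: list

    def __post_init__(self) -> None:
        if self.a_values.shape != self.b_values.shape:
            raise ValidationError(f"contrast {self.name!r}: unaligned sides")
        if self.a_values.shape[1] != len(self.pair_keys):
            raise ValidationError(f"contrast {self.name!r}: pair keys misaligned")
        if self.n_pairs < 2:
            raise ValidationError(
                f"contrast {self.name!r}: needs >= 2 pairs, got {self.n_pairs}"
            )

    @property
    def n_pairs(self) -> int:
        return self.a_values.shape[1]


def average_replicas(matrix: IntensityMatrix) -> IntensityMatrix:
    """Average technical replicas within each (mouse, tissue, zone) group.

    Zeros are included in the mean as values (a dropout halves the pair
    mean rather than being skipped).  Groups with a single replica pass
    through unchanged.  Output columns are named ``<mouse>_<zone>`` (or
    ``<mouse>_healthy``) with replica index 1.
    """
    ann = matrix.require_annotations()
    groups: dict[tuple, list[str]] = {}
    for name, row in ann.iterrows():
        key = (row["mouse_id"], row["tissue"], row["zone"], row["method"])
        groups.setdefault(key, []).append(str(name))

    cols = {}
    new_annotations = []
    for (mouse, tissue, zone, method), samples in groups.items():
        label = f"{mouse}_healthy" if tissue == "healthy_breast" else f"{mouse}_{zone}"
        cols[label] = matrix.values[samples].mean(axis=1)
        new_annotations.append(
            SampleAnnotation(
                sample_name=label,
                mouse_id=mouse,
                tissue=tissue,
                zone=zone,
                replica=1,
                method=method,
            )
        )
    averaged = IntensityMatrix(
        values=pd.DataFrame(cols, index=matrix.genes),
        protein_ids=matrix.protein_ids.copy(),
        extra_genes=matrix.extra_genes.copy(),
    )
    return averaged.attach_annotations(new_annotations)


def global_floor(matrix: IntensityMatrix) -> float:
    """Half the minimal strictly positive intensity in the whole dataset.

    This is the replacement value for zeros when forming fold-change
    ratios.  Undefined (error) for an all-zero matrix.
    """
    vals = matrix.values.to_numpy(dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValidationError("all intensities are zero; floor undefined")
    return 0.5 * float(positive.min())


def _select(ann: pd.DataFrame, selector: Mapping[str, str]) -> pd.DataFrame:
    sub = ann
    for field_name, value in selector.items():
        if field_name not in ann.columns:
            raise ValidationError(f"unknown annotation field {field_name!r}")
        sub = sub[sub[field_name] == value]
    return sub


def build_contrast(
    matrix: IntensityMatrix,
    name: str,
    group_a: Mapping[str, str],
    group_b: Mapping[str, str],
    pairing: Sequence[str] = ("mouse_id",),
) -> PairedContrast:
    """Assemble paired vectors for ``group_a`` vs ``group_b``.

    ``group_a``/``group_b`` are annotation selectors, e.g.
    ``{"tissue": "tumor", "zone": "center"}``.  Both groups must resolve
    to exactly one sample per pairing key and to identical key sets;
    unmatched keys are listed in the error.
    """
    ann = matrix.require_annotations()
    sides = {}
    for side, selector in (("a", group_a), ("b", group_b)):
        sub = _select(ann, selector)
        keyed: dict[tuple, str] = {}
        for sample_name, row in sub.iterrows():
            key = tuple(row[f] for f in pairing)
            if key in keyed:
                raise ValidationError(
                    f"contrast {name!r}: pairing key {key} matches several "
                    f"samples on side {side} ({keyed[key]!r}, {sample_name!r}); "
                    f"average replicas first or pair on replica too"
                )
            keyed[key] = str(sample_name)
        sides[side] = keyed
    only_a = sorted(set(sides["a"]) - set(sides["b"]))
    only_b = sorted(set(sides["b"]) - set(sides["a"]))
    if only_a or only_b:
        raise ValidationError(
            f"contrast {name!r}: unmatched pairing keys — missing partner for "
            f"{only_a + only_b}"
        )
    if not sides["a"]:
        raise ValidationError(f"contrast {name!r}: selectors match no samples")
    keys = sorted(sides["a"])
    a_cols = [sides["a"][k] for k in keys]
    b_cols = [sides["b"][k] for k in keys]
    return PairedContrast(
        name=name,
        genes=matrix.genes,
        a_values=matrix.values[a_cols].to_numpy(dtype=float),
        b_values=matrix.values[b_cols].to_numpy(dtype=float),
        pair_keys=keys,
    )


def tumor_vs_healthy_contrasts(
    matrix: IntensityMatrix, zones: Sequence[str] = ("center", "middle", "periphery")
) -> dict[str, PairedContrast]:
    """The zone-vs-healthy contrasts on the replica-averaged matrix.

    Returns ``{"<zone>_vs_healthy": PairedContrast}`` with one pair per
    mouse (the study's 5-dimensional vectors).
    """
    averaged = average_replicas(matrix)
    out = {}
    for zone in zones:
        cname = f"{zone}_vs_healthy"
        out[cname] = build_contrast(
            averaged,
            cname,
            group_a={"tissue": "tumor", "zone": zone},
            group_b={"tissue": "healthy_breast"},
            pairing=("mouse_id",),
        )
    return out


def zone_pair_contrasts(
    matrix: IntensityMatrix,
    pairs: Sequence[tuple] = ZONE_PAIRS,
    pairing_mode: str = "replica",
) -> dict[str, PairedContrast]:
    """The pairwise zone contrasts inside the tumor.

    With ``pairing_mode="replica"`` (default), replica r of zone A pairs
    with replica r of zone B within each mouse, yielding mice x replicas
    pairs (the study's 10-dimensional vectors).  ``pairing_mode="mean"``
    instead averages replicas first and pairs per mouse — exposed so the
    sensitivity of results to the pairing convention can be checked.
    """
    if pairing_mode == "replica":
        source, pairing = matrix, ("mouse_id", "replica")
    elif pairing_mode == "mean":
        source, pairing = average_replicas(matrix), ("mouse_id",)
    else:
        raise ValidationError(f"unknown pairing_mode {pairing_mode!r}")
    out = {}
    for zone_a, zone_b in pairs:
        cname = f"{zone_a}_vs_{zone_b}"
        out[cname] = build_contrast(
            source,
            cname,
            group_a={"tissue": "tumor", "zone": zone_a},
            group_b={"tissue": "tumor", "zone": zone_b},
            pairing=pairing,
        )
    return out
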