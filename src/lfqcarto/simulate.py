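"""Synthetic LFQ study generator with planted ground truth.

Emulates the study design the pipeline was built for: ``n_mice`` animals,
each contributing ``len(zones) * replicas_per_zone`` tumor samples (two
replicas at each of three spatial zones by default) plus one healthy-breast
sample, all from the same extraction method.

The model is additive on the log2 scale.  For protein g in sample s of
mouse m at zone z::

    log2 I[g, s] = baseline[g] + mouse[g, m]
                   + tumor_lfc[g] * [tissue(s) = tumor]
                   + zone_lfc[g, z]
                   + eps[g, s]

with ``I = 2 ** log2`` and each cell independently zeroed (dropout) with
probability ``dropout_rate`` (optionally abundance-dependent).  The
mouse term is shared between the tumor and healthy samples of a mouse, so
contrasts paired on the animal cancel it — the structure that makes the
paired t-test the right test downstream.

Planted tumor-wide and zone-specific effects are returned as
:class:`PlantedTruth` so downstream calls can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    IntensityMatrix,
    SampleAnnotation,
    ValidationError,
    write_lfq_table,
    write_sample_sheet,
    write_table,
)

__all__ = [
    "StudyConfig",
    "PlantedTruth",
    "RecoveryReport",
    "generate_study",
    "evaluate_recovery",
    "write_study",
]

ZONE_NAMES = ("center", "middle", "periphery")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Scales are log2: ``baseline_log2_mean``/``sd`` set the spread of
    protein abundances across the proteome, ``mouse_effect_sd`` the
    animal-to-animal shift shared within a mouse, ``residual_sd`` the
    per-measurement technical noise.  Fold-change magnitudes are planted
    uniformly inside the given |log2fc| ranges.  Tumor markers point up
    with probability ``tumor_up_fraction`` (default all up, as in the
    tumor the design emulates); zone markers draw their direction at
    random and record it in the truth.
    """

    n_mice: int = 5
    n_proteins: int = 4519
    zones: tuple = ZONE_NAMES
    replicas_per_zone: int = 2
    baseline_log2_mean: float = 23.0
    baseline_log2_sd: float = 2.0
    mouse_effect_sd: float = 0.3
    residual_sd: float = 0.15
    n_tumor_markers: int = 20
    tumor_log2fc_range: tuple = (3.0, 5.0)
    tumor_up_fraction: float = 1.0
    n_zone_markers_per_zone: int = 5
    zone_log2fc_range: tuple = (3.0, 5.0)
    dropout_rate: float = 0.05
    dropout_mode: str = "uniform"  # or "abundance" (logistic in log2 intensity)
    method: str = "ebiopsy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 2 or self.n_proteins < 1:
            raise ValidationError("need >= 2 mice and >= 1 protein")
        if self.replicas_per_zone < 1 or not self.zones:
            raise ValidationError("need >= 1 zone and >= 1 replica per zone")
        for sd in (self.baseline_log2_sd, self.mouse_effect_sd, self.residual_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        for lo, hi in (self.tumor_log2fc_range, self.zone_log2fc_range):
            if lo > hi:
                raise ValidationError("log2fc ranges must be ordered (lo <= hi)")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if not 0 <= self.tumor_up_fraction <= 1:
            raise ValidationError("tumor_up_fraction must be in [0, 1]")
        if self.dropout_mode not in ("uniform", "abundance"):
            raise ValidationError(f"unknown dropout_mode {self.dropout_mode!r}")
        n_markers = (
            self.n_tumor_markers + self.n_zone_markers_per_zone * len(self.zones)
        )
        if n_markers > self.n_proteins:
            raise ValidationError("more planted markers than proteins")

    def null(self) -> "StudyConfig":
        """The matching no-effect configuration: no markers, no dropout."""
        return dataclasses.replace(
            self, n_tumor_markers=0, n_zone_markers_per_zone=0, dropout_rate=0.0
        )


@dataclass
class PlantedTruth:
    """Ground truth of a generated study.

    ``tumor_markers`` maps gene -> signed log2 fold change (tumor over
    healthy, applied in every zone).  ``zone_markers`` maps gene ->
    (zone, direction, |log2fc|) where direction ``up`` means the gene is
    elevated in that zone relative to both others.
    """

    tumor_markers: dict = field(default_factory=dict)
    zone_markers: dict = field(default_factory=dict)

    @property
    def tumor_genes(self) -> set:
        return set(self.tumor_markers)

    def zone_genes(self, zone: str, direction: str) -> set:
        return {
            g
            for g, (z, d, _) in self.zone_markers.items()
            if z == zone and d == direction
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "kind": "tumor", "zone": "", "direction": "up" if fc > 0 else "down", "log2fc": fc}
            for g, fc in sorted(self.tumor_markers.items())
        ] + [
            {"gene": g, "kind": "zone", "zone": z, "direction": d, "log2fc": fc}
            for g, (z, d, fc) in sorted(self.zone_markers.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "kind", "zone", "direction", "log2fc"])


def generate_study(config: StudyConfig) -> tuple[IntensityMatrix, PlantedTruth]:
    """Generate one annotated intensity matrix plus its planted truth.

    Identical config (including seed) gives bitwise-identical output.
    Independent PRNG sub-streams are derived per model component so that,
    e.g., switching dropout off does not shift the noise draws.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_markers, rng_baseline, rng_mouse, rng_noise, rng_dropout = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    n_genes = cfg.n_proteins
    width = len(str(max(n_genes, 1)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])

    # --- planted effects ---------------------------------------------------
    n_zone_total = cfg.n_zone_markers_per_zone * len(cfg.zones)
    marker_idx = rng_markers.choice(
        n_genes, size=cfg.n_tumor_markers + n_zone_total, replace=False
    )
    tumor_idx = marker_idx[: cfg.n_tumor_markers]
    zone_idx = marker_idx[cfg.n_tumor_markers:]

    lo, hi = cfg.tumor_log2fc_range
    tumor_mag = rng_markers.uniform(lo, hi, size=cfg.n_tumor_markers)
    tumor_sign = np.where(
        rng_markers.random(cfg.n_tumor_markers) < cfg.tumor_up_fraction, 1.0, -1.0
    )
    tumor_lfc = np.zeros(n_genes)
    tumor_lfc[tumor_idx] = tumor_sign * tumor_mag

    zlo, zhi = cfg.zone_log2fc_range
    zone_lfc = {z: np.zeros(n_genes) for z in cfg.zones}
    truth = PlantedTruth(
        tumor_markers={
            genes[i]: float(fc) for i, fc in zip(tumor_idx, tumor_lfc[tumor_idx])
        }
    )
    for k, zone in enumerate(cfg.zones):
        idx = zone_idx[
            k * cfg.n_zone_markers_per_zone: (k + 1) * cfg.n_zone_markers_per_zone
        ]
        mags = rng_markers.uniform(zlo, zhi, size=len(idx))
        signs = rng_markers.choice([-1.0, 1.0], size=len(idx))
        zone_lfc[zone][idx] = signs * mags
        for i, s, m in zip(idx, signs, mags):
            truth.zone_markers[genes[i]] = (
                zone,
                "up" if s > 0 else "down",
                float(m),
            )

    # --- sample layout ------------------------------------------------------
    annotations: list[SampleAnnotation] = []
    for m in range(1, cfg.n_mice + 1):
        mouse = f"M{m}"
        for zone in cfg.zones:
            for r in range(1, cfg.replicas_per_zone + 1):
                annotations.append(
                    SampleAnnotation(
                        sample_name=f"{mouse}_{zone}_r{r}",
                        mouse_id=mouse,
                        tissue="tumor",
                        zone=zone,
                        replica=r,
                        method=cfg.method,
                    )
                )
        annotations.append(
            SampleAnnotation(
                sample_name=f"{mouse}_healthy",
                mouse_id=mouse,
                tissue="healthy_breast",
                zone="none",
                replica=1,
                method=cfg.method,
            )
        )
    n_samples = len(annotations)

    # --- assemble log2 intensities -----------------------------------------
    baseline = rng_baseline.normal(
        cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes
    )
    mouse_eff = rng_mouse.normal(
        0.0, cfg.mouse_effect_sd, size=(n_genes, cfg.n_mice)
    )
    mouse_index = {f"M{m}": m - 1 for m in range(1, cfg.n_mice + 1)}

    log2 = np.empty((n_genes, n_samples))
    for j, ann in enumerate(annotations):
        col = baseline + mouse_eff[:, mouse_index[ann.mouse_id]]
        if ann.tissue == "tumor":
            col = col + tumor_lfc + zone_lfc[ann.zone]
        log2[:, j] = col
    log2 += rng_noise.normal(0.0, cfg.residual_sd, size=(n_genes, n_samples))

    intensity = np.exp2(log2)

    if cfg.dropout_rate > 0:
        if cfg.dropout_mode == "uniform":
            drop = rng_dropout.random(intensity.shape) < cfg.dropout_rate
        else:
            # Logistic in log2 intensity, centred so the marginal dropout
            # rate matches dropout_rate at the baseline mean; low-abundance
            # proteins drop out more often, as in real LFQ data.
            logit0 = np.log(cfg.dropout_rate / (1 - cfg.dropout_rate))
            slope = 1.0  # per log2 unit below the proteome mean
            p = 1.0 / (
                1.0 + np.exp(-(logit0 + slope * (cfg.baseline_log2_mean - log2)))
            )
            drop = rng_dropout.random(intensity.shape) < p
        intensity = np.where(drop, 0.0, intensity)

    values = pd.DataFrame(
        intensity,
        index=pd.Index(genes, name="gene"),
        columns=[a.sample_name for a in annotations],
    )
    matrix = IntensityMatrix(
        values=values,
        protein_ids=pd.Series(
            [f"P{g[1:]}" for g in genes], index=values.index, name="protein_id"
        ),
        extra_genes=pd.Series("", index=values.index, name="extra_genes"),
    ).attach_annotations(annotations)
    return matrix, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Sensitivity and realized false-discovery proportion of a call set."""

    sensitivity: float
    fdp: float
    n_called: int
    n_planted: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _score(calls: set, planted: set) -> RecoveryReport:
    calls, planted = set(calls), set(planted)
    tp = len(calls & planted)
    sens = tp / len(planted) if planted else 1.0
    fdp = len(calls - planted) / max(len(calls), 1)
    return RecoveryReport(
        sensitivity=sens, fdp=fdp, n_called=len(calls), n_planted=len(planted)
    )


def evaluate_recovery(
    truth: PlantedTruth,
    tumor_calls: set | None = None,
    zone_calls: dict | None = None,
) -> dict:
    """Score downstream calls against the planted truth.

    ``tumor_calls`` is a set of genes; ``zone_calls`` maps
    ``(zone, direction)`` -> gene set.  Returns a dict of
    :class:`RecoveryReport`: key ``"tumor"``, one per (zone, direction)
    pair supplied, and ``"zones_overall"`` pooling all zone cells.
    Zone scoring is positional: a planted zone marker counts as recovered
    only in its own (zone, direction) cell.
    """
    report: dict = {}
    if tumor_calls is not None:
        report["tumor"] = _score(tumor_calls, truth.tumor_genes)
    if zone_calls is not None:
        pooled_calls: set = set()
        pooled_planted: set = set()
        for (zone, direction), calls in zone_calls.items():
            planted = truth.zone_genes(zone, direction)
            report[(zone, direction)] = _score(calls, planted)
            # pooled view tags genes with their cell so misplacement counts
            pooled_calls |= {(zone, direction, g) for g in calls}
            pooled_planted |= {(zone, direction, g) for g in planted}
        pooled = _score(pooled_calls, pooled_planted)
        report["zones_overall"] = pooled
    return report


def write_study(
    matrix: IntensityMatrix, truth: PlantedTruth, outdir: str | Path
) -> dict:
    """Write the study as the same TSV formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lfq_table": outdir / "lfq_table.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "planted_truth": outdir / "planted_truth.tsv",
    }
    write_lfq_table(matrix, paths["lfq_table"])
    write_sample_sheet(matrix.annotation_list(), paths["sample_sheet"])
    write_table(truth.to_frame(), paths["planted_truth"])
    return {k: str(v) for k, v in paths.items()}
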