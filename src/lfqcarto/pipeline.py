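"""End-to-end orchestration of the analysis stages.

Stages: simulate (optional) -> preprocess -> diffexpr -> biomarkers ->
cartography -> overabundance -> enrichment -> qc.  Every stage writes TSV
artifacts into the output directory and the run ends with a JSON manifest
listing each file with its SHA-256 hash, so identical inputs, config and
seed provably give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarkers as bm
from . import cartography as carto
from . import diffexpr as de
from . import enrichment as enr
from . import overabundance as oa
from . import preprocess as pp
from . import qc as qcmod
from .io import (
    IntensityMatrix,
    ValidationError,
    read_gmt,
    read_lfq_table,
    read_sample_sheet,
    write_table,
)
from .simulate import StudyConfig, generate_study, write_study

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lfqcarto")


@dataclass
class PipelineConfig:
    """Everything a run needs: paths, thresholds, flags, seed.

    Thresholds default to the study's conventions: strong biomarkers at
    per-test p < 0.01, potential biomarkers and zone specificity at
    p < 0.05, enrichment significance at exact mHG p < 1e-6.
    """

    lfq_table: str | None = None
    sample_sheet: str | None = None
    gene_sets: str | None = None
    simulate: StudyConfig | None = None
    strong_p: float = 0.01
    potential_p: float = 0.05
    zone_p: float = 0.05
    enrichment_p: float = 1e-6
    log_scale: bool = False
    zone_pairing: str = "replica"
    seed: int = 0

    def validate(self) -> None:
        for name in ("strong_p", "potential_p", "zone_p", "enrichment_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name}={v} must be in (0, 1)")
        if self.zone_pairing not in ("replica", "mean"):
            raise ValidationError(f"unknown zone_pairing {self.zone_pairing!r}")
        if self.simulate is None and (self.lfq_table is None or self.sample_sheet is None):
            raise ValidationError(
                "either a simulate block or lfq_table + sample_sheet paths required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("zones", "tumor_log2fc_range", "zone_log2fc_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = StudyConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig, outdir: Path) -> tuple[IntensityMatrix, list]:
    artifacts = []
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        matrix, truth = generate_study(sim_cfg)
        paths = write_study(matrix, truth, outdir / "simulate")
        artifacts.extend(paths.values())
        log.info(
            "simulated study: %d proteins x %d samples, %d tumor + %d zone markers",
            matrix.n_proteins,
            matrix.n_samples,
            len(truth.tumor_markers),
            len(truth.zone_markers),
        )
    else:
        matrix = read_lfq_table(config.lfq_table)
        annotations = read_sample_sheet(config.sample_sheet)
        matrix = matrix.attach_annotations(annotations)
        log.info(
            "loaded %d proteins x %d samples (%d input rows, %d dropped for "
            "invalid IDs)",
            matrix.n_proteins,
            matrix.n_samples,
            matrix.parse_report.get("input_rows", matrix.n_proteins),
            matrix.parse_report.get("dropped_invalid_id", 0),
        )
    return matrix, artifacts


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the artifact manifest (also written)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    matrix, sim_artifacts = _load_inputs(config, outdir)
    artifacts.extend(sim_artifacts)

    # --- preprocess --------------------------------------------------------
    floor = pp.global_floor(matrix)
    log.info("zero-replacement floor: %.6g", floor)
    tvh = pp.tumor_vs_healthy_contrasts(matrix)
    zvz = pp.zone_pair_contrasts(matrix, pairing_mode=config.zone_pairing)

    # --- differential expression -------------------------------------------
    results = {
        name: de.compare_groups(c, floor, log_scale=config.log_scale)
        for name, c in {**tvh, **zvz}.items()
    }
    de_frames = [r.to_frame() for r in results.values()]
    de_path = outdir / "diffexpr.tsv"
    write_table(pd.concat(de_frames, ignore_index=True), de_path)
    artifacts.append(str(de_path))

    # --- biomarkers ---------------------------------------------------------
    tvh_results = [results[n] for n in tvh]
    strong = bm.intersect_consistent(tvh_results, config.strong_p)
    potential = bm.intersect_consistent(tvh_results, config.potential_p)
    for label, s in (("strong", strong), ("potential", potential)):
        log.info(
            "%s biomarkers: %d genes at p<%g in all %d contrasts "
            "(per-contrast counts %s); composite FDR = %s; HGT p = %.3g",
            label,
            s.intersection_size,
            s.p_threshold,
            s.k_comparisons,
            s.per_comparison_counts,
            "NA" if s.composite_fdr is None else f"{s.composite_fdr:.3g}",
            s.hgt_p,
        )
    bio_rows = []
    for label, s in (("strong", strong), ("potential", potential)):
        for gene in sorted(s.genes):
            bio_rows.append(
                {"set": label, "gene": gene, "direction": s.directions[gene]}
            )
    bio_path = outdir / "biomarkers.tsv"
    write_table(
        pd.DataFrame(bio_rows, columns=["set", "gene", "direction"]), bio_path
    )
    summary_rows = [
        {
            "set": label,
            "p_threshold": s.p_threshold,
            "k_comparisons": s.k_comparisons,
            "per_comparison_counts": ";".join(map(str, s.per_comparison_counts)),
            "intersection_size": s.intersection_size,
            "composite_fdr": float("nan") if s.composite_fdr is None else s.composite_fdr,
            "hgt_p": s.hgt_p,
        }
        for label, s in (("strong", strong), ("potential", potential))
    ]
    bio_summary_path = outdir / "biomarkers_summary.tsv"
    write_table(pd.DataFrame(summary_rows), bio_summary_path)
    artifacts.extend([str(bio_path), str(bio_summary_path)])

    # --- cartography --------------------------------------------------------
    zone_calls = carto.zone_specific_calls(
        {n: results[n] for n in zvz}, config.zone_p
    )
    cmap = carto.build_cartography(
        zone_calls,
        potential.genes,
        N=matrix.n_proteins,
        p_zone=config.zone_p,
        p_marker=config.potential_p,
    )
    for zone, fdr in cmap.combined_fdr.items():
        log.info(
            "cartography %s: up=%d down=%d combined FDR=%s",
            zone,
            cmap.zone_counts[zone][0],
            cmap.zone_counts[zone][1],
            "NULL" if fdr is None else f"{fdr:.3g}",
        )
    carto_path = outdir / "cartography_map.tsv"
    write_table(cmap.to_map_frame(), carto_path)
    zone_rows = []
    for (zone, direction), genes_p in sorted(zone_calls.cells.items()):
        for gene, max_p in sorted(genes_p.items()):
            zone_rows.append(
                {"zone": zone, "direction": direction, "gene": gene, "max_p": max_p}
            )
    zone_path = outdir / "zone_specific_calls.tsv"
    write_table(
        pd.DataFrame(zone_rows, columns=["zone", "direction", "gene", "max_p"]),
        zone_path,
    )
    artifacts.extend([str(carto_path), str(zone_path)])

    # --- overabundance ------------------------------------------------------
    oa_frames = []
    for name, r in results.items():
        curve = oa.overabundance_curve(r.nondegenerate()["p_value"])
        frame = curve.to_frame()
        frame.insert(0, "contrast", name)
        oa_frames.append(frame)
    oa_path = outdir / "overabundance.tsv"
    write_table(pd.concat(oa_frames, ignore_index=True), oa_path)
    artifacts.append(str(oa_path))

    # --- enrichment ---------------------------------------------------------
    enr_rows = []
    if config.gene_sets is not None:
        collection = read_gmt(config.gene_sets)
        for name in tvh:
            for direction in enr.DIRECTIONS:
                ranked = enr.rank_by_tstat(results[name], direction)
                found, skipped = enr.enrich_gene_sets(
                    ranked, collection, config.enrichment_p
                )
                if skipped:
                    log.info(
                        "enrichment %s/%s: skipped sets outside universe: %s",
                        name,
                        direction,
                        skipped,
                    )
                for res in found:
                    enr_rows.append(
                        {
                            "contrast": name,
                            "direction": direction,
                            "set": res.set_name,
                            "N": res.N,
                            "B": res.B,
                            "cutoff": res.cutoff,
                            "mhg_stat": res.mhg_stat,
                            "exact_p": res.exact_p,
                            "significant": res.significant,
                        }
                    )
    enr_path = outdir / "enrichment.tsv"
    write_table(
        pd.DataFrame(
            enr_rows,
            columns=[
                "contrast",
                "direction",
                "set",
                "N",
                "B",
                "cutoff",
                "mhg_stat",
                "exact_p",
                "significant",
            ],
        ),
        enr_path,
    )
    artifacts.append(str(enr_path))

    # --- qc -----------------------------------------------------------------
    report = qcmod.sample_correlations(matrix)
    qc_path = outdir / "qc_correlations.tsv"
    write_table(report.pairs, qc_path)
    qc_summary_path = outdir / "qc_correlation_summary.tsv"
    write_table(report.mouse_averages().reset_index(), qc_summary_path)
    artifacts.extend([str(qc_path), str(qc_summary_path)])
    grand = report.grand_average()
    log.info(
        "grand-average within-mouse correlation: pearson=%.3f spearman=%.3f",
        grand["pearson"],
        grand["spearman"],
    )

    # --- manifest -----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "files": {
            str(Path(p).relative_to(outdir)): _sha256(Path(p)) for p in artifacts
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
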