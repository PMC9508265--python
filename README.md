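# lfqcarto

Spatial differential proteomics from label-free quantification (LFQ)
intensity tables.

The package is built for paired multi-zone tumor sampling designs: each
animal contributes replicate tumor samples at several spatial zones
(center / middle / periphery) plus one healthy-tissue sample, quantified
as a MaxQuant-style protein-by-sample LFQ table. From that input it
produces:

* **tumor-vs-healthy biomarker calls** — genes significant with a
  consistent sign in *every* zone-vs-healthy paired t-test
  simultaneously, with two closed-form significance summaries:
  the composite FDR `N·∏pᵢ^kᵢ/m` (intersections expected by chance over
  observed) and an exact hypergeometric-tail (HGT) upper bound
  `P(X ≥ m), X ~ HG(N, K, n)` on the multi-way intersection, computed in
  log space;
* **an intratumor heterogeneity map** — genes differential in a single
  zone against both others, intersected with the potential-biomarker
  set, with the combined FDR `N·p_zone²·p_marker³/m` per zone;
* **overabundance diagnostics** — observed counts of tests with `p ≤ t`
  against the uniform-null expectation `N·t`, per contrast;
* **mHG gene-set enrichment** — genes ranked by t statistic, each GMT
  set scored by the minimum hypergeometric statistic
  `min_n HGT(N, B, n, b_n)` over list prefixes with an *exact* p-value
  for the optimized cutoff, computed by dynamic programming over the
  (prefix, hits) lattice;
* **QC** — within-animal Pearson/Spearman sample correlations and
  unique/shared protein-capture counts between extraction methods;
* **a synthetic study generator** — log-normal intensities with
  animal-paired structure, planted tumor-wide and zone-specific effects,
  and zero-inflation (dropout), with ground truth returned for recovery
  scoring, so every stage is testable without any external data.

Statistical conventions (zero handling, replica pairing, degenerate
tests, thresholds) are documented in [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic study at the default design size (5 mice, 3 zones ×
2 replicas + healthy, 4,519 proteins, 20 planted tumor markers, 5 zone
markers per zone) and call biomarkers:

```python
import lfqcarto as lc
from lfqcarto.preprocess import global_floor, tumor_vs_healthy_contrasts
from lfqcarto.diffexpr import compare_groups

cfg = lc.StudyConfig(seed=1)
matrix, truth = lc.generate_study(cfg)
floor = global_floor(matrix)
tvh = {n: compare_groups(c, floor)
       for n, c in tumor_vs_healthy_contrasts(matrix).items()}

strong = lc.intersect_consistent(list(tvh.values()), 0.01)
print(f"strong biomarkers: {strong.intersection_size} genes "
      f"(per-contrast counts {strong.per_comparison_counts})")
print(f"composite FDR = {strong.composite_fdr:.3g}, HGT p = {strong.hgt_p:.3g}")

report = lc.evaluate_recovery(truth, tumor_calls=strong.genes)["tumor"]
print(f"recovery vs planted truth: sensitivity={report.sensitivity:.2f}, "
      f"FDP={report.fdp:.2f}")
```

prints

```
strong biomarkers: 20 genes (per-contrast counts [36, 41, 48])
composite FDR = 0.000226, HGT p = 3.68e-34
recovery vs planted truth: sensitivity=1.00, FDP=0.00
```

The 20 genes significant at p < 0.01 in all three zones are exactly the
20 planted markers; 4519·0.01³/20 ≈ 2.3e−4 expected chance intersections
per observed call, and the tiny HGT p says an overlap of 20 among
per-zone significant sets of 36/41/48 genes cannot be coincidental.

Mapping intratumor heterogeneity on the same study (zone-specific calls
at p < 0.05, here intersected with the full gene universe):

```python
from lfqcarto.preprocess import zone_pair_contrasts

zvz = {n: compare_groups(c, floor)
       for n, c in zone_pair_contrasts(matrix).items()}
calls = lc.zone_specific_calls(zvz, 0.05)
cmap = lc.build_cartography(calls, set(matrix.genes), N=matrix.n_proteins)
for zone, (n_up, n_down) in cmap.zone_counts.items():
    fdr = cmap.combined_fdr[zone]
    print(f"{zone}: up={n_up} down={n_down} "
          f"combined_fdr={'NULL' if fdr is None else format(fdr, '.2g')}")
```

prints

```
center: up=7 down=8 combined_fdr=9.4e-05
middle: up=6 down=8 combined_fdr=0.0001
periphery: up=10 down=13 combined_fdr=6.1e-05
```

and all 15 planted zone markers land in their correct (zone, direction)
cell. The same pipeline runs from the shell:

```sh
lfqcarto simulate --out study/ --seed 1
lfqcarto run-all --config config.yaml --out results/ --seed 1
```

`run-all` writes every stage's TSV plus `manifest.json` with a SHA-256
hash per artifact; identical config and seed reproduce identical hashes.

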