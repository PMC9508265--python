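# Methods

`lfqcarto` analyses spatial differential protein expression from
label-free quantification (LFQ) intensity tables, in a paired multi-zone
tumor sampling design: each animal contributes technical-replicate tumor
samples at three spatial zones (center, middle, periphery) and one
healthy-tissue sample. This note records the statistical model, the
conventions at every decision point, and what the synthetic generator
does and does not emulate.

## Paired differential testing

Protein representations are paired within animal:

* **zone vs healthy** — the two technical replicas of a zone are averaged
  (zeros included as values), and each mouse's zone mean is paired with
  that mouse's healthy sample, giving n = #mice pairs;
* **zone vs zone** — replica r of zone A pairs with replica r of zone B
  in the same mouse, giving n = #mice × #replicas pairs. The replica
  pairing convention is index-matched (r↔r); a `pairing_mode="mean"`
  flag averages replicas first instead, so the sensitivity of results to
  this convention can be checked.

Each protein is tested with the plain two-sided paired Student t-test on
the **raw** LFQ values (t = mean(d) / (sd(d)/√n), d = a − b, sample sd,
df = n − 1). A log2 option exists (`log_scale=True`) but is off by
default: the raw-scale test is the pipeline's reference behaviour.
Degenerate rows (zero variance of d) are kept in output tables, flagged,
and excluded from ranking and intersection counting; identical vectors
get p = 1, a constant nonzero shift gets p = 0, both with t = 0.

Fold change is the geometric mean of the per-pair a/b ratios,
(∏ aᵢ/bᵢ)^(1/n), after replacing zeros with the **global floor**: half
the minimal strictly positive intensity of the whole dataset. Zeros are
ordinary values everywhere else (averaging, testing, correlation); only
ratio formation uses the floor.

## Intersection biomarker calling

A gene is called a tumor biomarker when its zone-vs-healthy test is
significant with a consistent sign in **every** zone simultaneously
(up: p < α and t > 0 in all three; down: mirrored). Two significance
summaries accompany a call set over a universe of N proteins:

* **composite FDR** = N · ∏ pᵢ^{kᵢ} / m — intersections expected by
  chance over intersections observed, where each threshold pᵢ was applied
  in kᵢ simultaneous tests and m genes were observed. Reported uncapped
  (it is a ratio, not a probability).
* **HGT bound** — with per-contrast significant counts c₁ ≤ c₂ ≤ …, the
  hypergeometric tail P(X ≥ m) for X ~ HG(N, K = c₂, n = c₁) is an upper
  bound on the k-way intersection probability (each extra contrast only
  shrinks the intersection). The tail is computed exactly in log space
  (log-gamma binomial terms combined with log-sum-exp), so desk-scale
  values like 1e−6 retain full precision.

Default thresholds: α = 0.01 for "strong" biomarkers, α = 0.05 for the
"potential" set used downstream by the cartography stage.

## Heterogeneity cartography

A gene is specific to a zone when both pairwise contrasts involving that
zone are significant (p < 0.05 by default) with the sign pointing the
same way; the third contrast is not relevant. Zone calls are intersected
— by membership alone, not direction — with the potential-biomarker set,
because a tumor-overexpressed gene may still be the *low* zone inside
the tumor. The combined FDR per zone stacks both criteria:
N · p_zone² · p_marker³ / m.

One gene may legitimately occupy two cells of the full table (up in one
zone and down in another is geometrically consistent). The single-zone
map keeps each gene only in its strongest cell — smallest max-p over the
two defining contrasts — and renders empty cells as NULL; the table
output keeps every qualifying assignment.

## Overabundance diagnostics

For each contrast the curve records, at every distinct observed p-value
t, the count of tests with p ≤ t against N·t expected under a uniform
null of independent tests. No dependence correction is applied — the
null is the face-value random model. The `within_null_band` check uses
the binomial band mean ± z·√(N t (1−t)), evaluated only where the
expected count is ≥ 10, because below that the normal approximation and
the discreteness of counts make a pointwise band meaningless.
`max_enrichment` likewise only scans thresholds with expected ≥ 1.

## mHG enrichment

Genes of a contrast (non-degenerate rows only — the proteins actually
detected and testable in both groups, which is the enrichment universe)
are ranked by t statistic: decreasing for overexpression, increasing for
underexpression, ties broken lexicographically by gene id so the order
is a deterministic total order. The two directions are always separate
ranked lists; there is no two-sided scan.

For a set occupying B of N positions, the **mHG statistic** is
min over n ∈ 1..N−1 of HGT(N, B, n, b_n), b_n = members in the first n
positions. Because the cutoff is optimized, the raw minimum is
anti-conservative; the **exact p-value** is the probability that a
uniformly random placement of the B members achieves a statistic at
least as small. It is computed by dynamic programming over the
(prefix, hits) lattice: paths step with hypergeometric probabilities
((B−b)/(N−n) for a member), mass entering the rejection region
{(n, b): HGT ≤ stat} is absorbed, and the absorbed total is the p-value.

Numerics: all DP quantities are probabilities in [0, 1], so plain double
precision suffices (no rescaling needed). The scan and the DP boundary
read one shared tail table — an (N+1)×(B+1) matrix of upper tails
accumulated right-to-left in log space — so their values are
bit-identical; the region boundary additionally allows a 1e−9 relative
epsilon so tails equal to the statistic up to float rounding count as
inside. Degenerate sets (B = 0 or B = N) scan flat at 1.0 and any
stat < 1 has exact p = 0. Complexity is O(N·B) time and memory per set.

## Quality control

Pearson and Spearman correlations are computed between the full LFQ
profiles of every sample pair within a mouse (zeros included; a
`nonzero_only` flag restricts to co-detected proteins), averaged per
mouse and then across mice so animals weigh equally. Pairs with a
constant profile are undefined and excluded from averages. Capture
comparison between two matrices counts proteins uniquely detected
(intensity > 0) by each side and by both; pooled scope treats a protein
as present when any sample of the group is positive.

## Synthetic study generator

The generator emulates the design the pipeline targets: 5 mice ×
(3 zones × 2 replicas + 1 healthy) = 35 samples over 4,519 proteins by
default. Log2 intensity is additive —
baseline_g + mouse_{g,m} + tumor_lfc_g·[tumor] + zone_lfc_{g,z} + ε —
with intensity = 2^log2 and independent Bernoulli dropout (an
abundance-dependent logistic mode exists, since real LFQ dropout is
abundance-dependent). The mouse term is shared between a mouse's tumor
and healthy samples, which is exactly the structure the paired test
exploits; with mouse_effect_sd > residual_sd, between-mouse variance
exceeds within-mouse variance (tested).

Default parameters, all log2 scale: baseline mean 23, baseline sd 2
(proteome-wide abundance spread), mouse effect sd 0.3, residual sd 0.15,
dropout 5%, 20 tumor markers with |log2fc| ∈ [3, 5], 5 zone markers per
zone with |log2fc| ∈ [3, 5]. Two deliberate choices:

* **Noise scales.** The raw-scale paired t-test assumes roughly normal
  paired differences. Large animal effects make the null differences a
  scale mixture (heavy-tailed across mice), which distorts the p-value
  distribution of a no-effect study away from uniform. The defaults are
  set where the null study is calibrated — rejection at 5% within
  binomial error and overabundance curves inside the 3-SE band — so that
  deviations seen on simulated data mean planted signal, not test-model
  mismatch. Real LFQ data is typically noisier; the generator's job is a
  correct testbed, not a fitted replica (no variance components are
  published for the motivating dataset).
* **Marker directions.** Tumor markers are planted upward by default
  (`tumor_up_fraction` configurable): the emulated study observed only
  overexpressed proteins at its strong threshold, and an underexpressed
  marker is destroyed by a single healthy-sample dropout shared by all
  three contrasts, so a mixed-sign default would make recovery depend
  mostly on dropout luck. Zone markers draw directions at random.

What the generator does **not** emulate: peptide-level quantification and
shared peptides, normalization artifacts, correlated dropout, batch or
acquisition-order effects, and any real biological covariance between
proteins. Passing recovery tests therefore demonstrates the calling
machinery is correct under the declared model, not that the thresholds
are optimal for real tissue data.

## Determinism and problem sizes

One root seed drives the generator through spawned sub-streams per model
component; the pipeline writes a SHA-256 manifest of every artifact and
identical config + seed reproduces identical hashes. Validation suites
run the null calibration at 2,500 proteins, marker recovery at the full
design size (4,519 × 35), the HGT enumeration oracle exhaustively to
N = 30 and the mHG enumeration oracle exhaustively to N = 12 — sizes at
which exact combinatorial oracles are feasible while exercising the same
code paths used at scale.

## Known limitations

* The composite FDR is the study's own closed-form expected/observed
  ratio, not a Benjamini–Hochberg-style procedure; it assumes
  independence across contrasts and is reported uncapped.
* The HGT intersection bound uses only the two smallest per-contrast
  counts; it is an upper bound, not an exact k-way intersection p-value.
* Raw-scale t-testing is faithful to the reference pipeline but is
  sensitive to heavy-tailed intensity noise; the log2 flag is the robust
  alternative when calibration on real data fails.
* GO-style analyses require the user to supply gene sets as GMT; no
  ontology graph propagation or term de-redundancy is performed.
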