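# Methods

## Whole-tumor voxel assembly

A case consists of a 3-D ADC map (10⁻⁶ mm²/s), a boolean include mask
(per-slice tumor ROIs rasterized on the ADC grid) and an optional exclude
mask for definite cystic, necrotic or hemorrhagic regions. The analysis
sample is the value of every voxel in `include & ~exclude`, pooled across
slices in a fixed slice-major, then row-major scan order; all downstream
features are functions of this one sample (first-order) or of its spatial
arrangement (GLCM). Masks are voxel rasters, not contours — rasterization is
assumed done upstream. Shape mismatches, missing files and fully excluded
tumors raise distinct error types.

## First-order features

* **Histogram** — fixed bin width (default 1 × 10⁻⁶ mm²/s) with edges at
  integer multiples of the width, so bins align across cases. Each bin is
  expressed as percent of total lesion volume; the cumulative curve ends at
  100%.
* **Percentiles** — nearest-rank (lower) definition: the smallest sample
  value with at least p% of voxels at or below it, i.e. the point with p% of
  the cumulative histogram to its left. No interpolation by default (a
  linear-interpolation variant sits behind a flag); with integer-valued ADC
  maps and unit bins the difference is negligible.
* **Moments** — mean; skewness and kurtosis use the bias-corrected sample
  formulas of common desktop statistics packages, with kurtosis reported as
  *excess* (normal → 0). Computed on raw voxel values, not the binned
  histogram. A constant sample has undefined shape moments and returns NaN
  (guarded, no exception) so degenerate phantoms flow through the pipeline;
  n < 3 (skewness) or n < 4 (kurtosis) is an error.

## GLCM entropy

Effective tumor voxels are quantized to G levels by linear min–max scaling
over the tumor's own range — `floor(G·(v−min)/(max−min))` clamped to G−1 —
so entropy measures *within-tumor* heterogeneity irrespective of absolute
ADC level. Defaults: G = 64, log base 2 (bits). Both are configurable; no
single convention is universal, and entropy magnitudes are only comparable
at fixed G.

Co-occurrences are accumulated for four in-plane distance-1 offsets
(0°, 45°, 90°, 135°), symmetrically, with both pair endpoints required to be
effective voxels on the same slice. Through-plane offsets are excluded
because ROIs are drawn per slice and slice spacing is anisotropic relative
to in-plane resolution. Counts from all slices and offsets are pooled into
one matrix and normalized once — a single whole-tumor statistic rather than
an average of per-slice entropies.

Two readings are computed side by side: joint (Haralick) entropy
−ΣΣ P(i,j) log P(i,j), the pipeline default and the field-standard "GLCM
entropy", and the marginal entropy −Σ P_x(i) log P_x(i) of the row sums.
Joint entropy is bounded by 2·log₂G, marginal by log₂G, and marginal ≤ joint
always.

## Statistics layer

* **ROC** — empirical curve over all achievable cutoffs; candidate
  thresholds are midpoints between adjacent distinct values plus the two
  extremes, which realizes every confusion table while placing the decision
  boundary centrally in its separating gap (the choice that generalizes to
  held-out cases). Direction is auto-chosen so AUC ≥ 0.5. AUC equals the
  normalized Mann–Whitney U (ties half credit); the 95% CI and the test
  against AUC = 0.5 use the DeLong placement-variance estimator with a
  normal approximation, clipped to [0, 1].
* **Cutoff** — Youden index (sensitivity + specificity − 1) maximization,
  ties broken toward higher specificity. Sensitivity/specificity/accuracy
  are reported in percent at one-decimal precision.
* **AUC comparison** — DeLong paired test on the placement covariance; a
  zero-variance zero-difference degenerates to p = 1.
* **LOOCV** — the cutoff *and* direction are re-estimated on each n−1
  training fold; the held-out case is classified by that fold's rule. A
  one-class training fold falls back to the fold majority (logged, not
  fatal). Note that a Youden-optimal cutoff does not maximize raw accuracy:
  under a label-independent feature its LOOCV accuracy settles near the 50%
  balanced level, not at the majority-class rate — the null reference used
  when judging "above chance".
* **Group tests** — classical pooled-variance unpaired t-test (Welch behind
  a flag), one-way ANOVA, and Tukey HSD pairwise post-hoc performed only
  when the overall ANOVA is significant (default α = 0.05); with two groups
  F = t² exactly.
* **McNemar** — exact binomial on discordant pairs, two-sided; χ² variants
  are avoided since discordant counts are small at n = 40.
* **Regression** — ordinary least squares; R² is the squared Pearson
  correlation, p the two-sided slope test.

## Synthetic phantom cohorts

Each phantom is a spherical tumor (default radius 12 mm) in a
48 × 48 × 20 grid at 1.5 × 1.5 × 3 mm voxels (~1000 tumor voxels),
embedded in a uniform background (900 × 10⁻⁶ mm²/s). Tumor voxels are
assigned to ADC mixture components by thresholding a Gaussian random field
smoothed to a spatial correlation length (empirical-quantile thresholds, so
component proportions are exact); white noise is added everywhere. The
necrosis exclusion blob is the contiguous set of tumor voxels nearest an
off-center seed point, sized to the requested fraction (default 8%) —
contiguous rather than salt-and-pepper so exclusion handling of pair
neighborhoods is genuinely exercised. Identical spec + seed is
bit-reproducible.

The cohort generator draws 8/10/22 cases in classes II/III/IV and maps a
single per-class heterogeneity parameter h (defaults 0.5 / 1.0 / 2.0,
strictly increasing by contract) onto the texture knobs. Because
quantization is per-tumor min–max, mixture *contrast* moves joint entropy
non-monotonically (concentrating mass at extreme levels eventually lowers
it), so h is mapped into the jointly monotone regime found by calibration
sweeps: component half-spread 100 + 50·h ADC units, correlation length
6/h² mm (clipped to [1.2, 30]), noise SD 120·(0.5 + 0.5·h). A lognormal
per-case jitter on h (σ = 0.2) and on the low-tail weight (σ = 0.4), a
per-case tumor center mean ~N(1300, 250) and radius jitter (±15%) provide
within-class spread. The low-ADC mixture tail (mean ~N(700, 120), weight
0.02 / 0.05 / 0.08 by class) deepens with class, pulling the fifth
percentile down, while class mean ADC differences stay small relative to
the between-case spread — so mean ADC does not separate classes. The
proliferation index (Ki-67 analog, percent) is −2 + 8·h + N(0, 6) clipped
to [0, 100].

At these defaults (20-seed validation): per-grade mean entropy is ordered
II < III < IV in ≈19/20 cohorts, entropy and fifth-percentile AUCs are both
≈0.85 with entropy ahead in about half the replicates, entropy LOOCV
accuracy ≈79%, and the mean-ADC t-test is non-significant in ≈19/20
cohorts.

**What the phantoms do not emulate:** MR acquisition physics (b-value
encoding, EPI distortion, eddy currents), anatomical brain context, partial
volume at tumor margins, peritumoral edema with graded infiltration,
irregular (non-spherical) tumor shapes, and rater variability in manual
delineation. Passing tests therefore demonstrate that the *computational
pipeline* behaves correctly on data with the assumed statistical structure
— not that the published clinical effect sizes are reproduced, which would
require the original patient volumes.

## Numerical choices and degenerate inputs

Pair-count normalization is exact (counts → probabilities once, tolerance
1e-9 on Σ P = 1); 0·log 0 ≡ 0; a constant tumor yields entropy 0,
percentile = the constant and NaN shape moments; a single-voxel tumor has
no pairs and is an error; quantization of a constant region maps to level
0. Seeds derive from a single `numpy` Generator per phantom/cohort, keeping
every output a pure function of (spec, seed).

## Problem sizes

Default cohorts are 40 cases of ~1000 tumor voxels; replicate-based checks
use 20 cohort replicates and the null LOOCV reference uses 200 simulated
replicates at n = 40 — sizes at which all Monte-Carlo acceptance margins
are several standard errors wide while the full suite runs in well under a
minute of compute.

## Known limitations

* Entropy magnitudes depend on G and on the joint-vs-marginal convention;
  cross-study comparison requires matching both.
* The DeLong CI uses a normal approximation on the AUC scale; near-perfect
  separation at small n makes it conservative (clipped at 1.0) rather than
  logit-transformed.
* Tukey post-hoc p-values come from statsmodels' studentized-range
  implementation; "p < 0.05 / > 0.05"-style gating mirrors common clinical
  reporting rather than providing exact tiny p-values for all pairs.
* The proliferation link is linear in class heterogeneity by construction;
  it supports the regression stage but carries no biological dose-response
  claim.
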