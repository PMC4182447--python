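# adc-texture

Whole-tumor texture and histogram analysis of apparent diffusion coefficient
(ADC) maps for glioma grading.

## The problem

Gliomas range from low-grade (WHO II) to high-grade (WHO III/IV), and grade
drives therapy. Diffusion-weighted MRI yields ADC maps (units of
10⁻⁶ mm²/s) in which dense, highly cellular tumor shows low diffusivity —
but the *mean* ADC of a tumor is an unreliable grade marker because gliomas
are spatially heterogeneous: necrosis, edema and cellular foci push the
signal in opposite directions. Two whole-tumor summaries do better:

* **GLCM entropy** — a second-order texture statistic quantifying spatial
  irregularity. Tumor voxels (all slices pooled, with definite
  cystic/necrotic/hemorrhagic areas excluded) are quantized to *G* gray
  levels between the tumor's own min and max; a gray-level co-occurrence
  matrix *P(i, j)* counts in-plane neighbor pairs at distance 1 in four
  directions; entropy is

  H = −Σᵢ Σⱼ P(i, j) log₂ P(i, j)

  (the entropy of the marginal P_x(i) = Σⱼ P(i, j) is computed alongside).
  Higher entropy = more heterogeneous texture = higher grade.
* **Fifth-percentile ADC** — the point with 5% of the cumulative
  voxel histogram to its left; a surrogate for the most cellular subregion,
  which *falls* with grade.

The package implements the full analysis for radiologists and imaging
scientists: voxel assembly from NIfTI volumes and per-slice ROI masks,
percentage/cumulative histograms, first-order moments (mean, skewness,
excess kurtosis), GLCM entropy, and the diagnostic-statistics layer —
empirical ROC curves with DeLong AUC confidence intervals, Youden-index
cutoffs, paired DeLong AUC comparison, leave-one-out cross-validation of the
cutoff classifier, the exact McNemar test, pooled-variance t-tests, one-way
ANOVA with gated Tukey HSD post-hoc, and Pearson regression against a Ki-67
proliferation index.

Because no patient data are distributed, a synthetic phantom generator
produces graded 40-case cohorts (8 / 10 / 22 cases in grade-like classes
II/III/IV) whose texture irregularity and low-ADC tail increase with class
while class mean ADC stays statistically indistinguishable — the regime the
analysis is designed for.

## Worked example

```python
from adc_texture import CohortSpec, generate_cohort
from adc_texture.pipeline import build_feature_table
from adc_texture.stats import roc_analysis, youden_cutoff, loocv_accuracy

df = build_feature_table(generate_cohort(CohortSpec(base_seed=1)))
y = (df.grade_binary == "high").to_numpy()
roc = roc_analysis(df.entropy_joint.to_numpy(), y)
cut = youden_cutoff(roc)
loo = loocv_accuracy(df.entropy_joint.to_numpy(), y)
print(f"entropy AUC {roc.auc:.3f} (95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f})")
print(f"cutoff {cut.rule}: sens {cut.sensitivity:.1f}%, spec {cut.specificity:.1f}%, acc {cut.accuracy:.1f}%")
print(f"LOOCV accuracy {loo.accuracy:.1f}%")
```

prints

```
entropy AUC 0.887 (95% CI 0.767-1.000)
cutoff positive if value > 9.70989: sens 90.6%, spec 75.0%, acc 87.5%
LOOCV accuracy 85.0%
```

GLCM entropy of the 40 synthetic tumors separates low- from high-grade
cases with AUC 0.89; the single Youden cutoff (call high-grade when entropy
exceeds 9.71 bits) classifies 87.5% of cases correctly in-sample and 85%
under leave-one-out validation. In the same cohort the per-grade mean
entropy rises II → III → IV while mean ADC does not order with grade.

## Command line

```sh
adc-texture synth --config cohort.yaml --out cohort/ --seed 5   # NIfTI + manifest
adc-texture run --config pipeline.yaml                          # full report bundle
adc-texture features --volume case_adc.nii.gz --mask case_mask.nii.gz
synth-cohort --out cohort/ --seed 5                             # standalone alias
```

`adc-texture run` writes `features.csv`, per-case histogram CSVs, four
report tables (group comparisons, per-grade ANOVA, ROC summaries, the
Ki-67 regressions) and `report.md` with a full config/version provenance
header. Identical config + seed reproduces a byte-identical feature table.

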