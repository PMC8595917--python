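# deltarad

Delta-radiomics assessment of thermal-ablation response on paired CT, with
survival analysis of local tumor progression.

## The problem

When a lung tumor is treated with percutaneous microwave ablation (MWA), a CT
scan is acquired immediately after the procedure with the same position and
scan parameters as the planning scan. Although the lesion's volume barely
changes acutely, its internal density structure does: dehydration and protein
denaturation drive the mean Hounsfield-unit (HU) density down while intratumor
heterogeneity rises. `deltarad` quantifies that immediate change and asks two
clinical questions:

1. does the change predict the visual response score read from the 1-month
   contrast-enhanced CT, and
2. does it predict local tumor progression (LTP) during follow-up?

The package is aimed at imaging researchers who have paired pre/post volumes
with tumor masks (NIfTI, or a DICOM series) and a cohort table of response
readings and follow-up, and at method developers who need a fully synthetic,
ground-truthed test bed for delta-radiomics pipelines.

## The statistics at the core

For each of 19 features computed inside the tumor ROI of both scans
(P1 = pre-ablation value, P2 = immediate post-ablation value), the change
statistic is

```
ΔP = (P2 − P1) / P1 × 100  [%]
```

Features span three scales, all computed in full 3D:

* **global** — first-order HU histogram statistics (mean, median, P10,
  robust mean absolute deviation, kurtosis = m₄/m₂², population variance);
* **regional** — gray-level size-zone (GLSZM, 26-connected zones: zone
  percentage, small/large-area emphasis) and run-length (GLRLM, 13
  directions: short/long-run low-gray-level emphasis) statistics;
* **local** — gray-level co-occurrence (GLCM, 13 directions merged,
  symmetric, distance 1: contrast, cluster tendency/prominence, joint
  energy/entropy, maximum probability, correlation, sum of squares), plus
  NGTDM coarseness/busyness/contrast as optional extras.

The visual response score `Rvisu` follows an mRECIST-style rubric
(5 = complete ablation with shrinkage … 2 = residual ≥50% or a new enhancing
zone), averaged over three observers; a mean ≥ 4 defines complete ablation.
Analysis proceeds with Shapiro–Wilk-gated paired tests of P2 vs P1, Spearman
correlation of ΔP with Rvisu, Kaplan–Meier/log-rank comparisons of
dichotomized groups (e.g. Δcontrast% > 30.5%), separate-entry multivariate
Cox proportional-hazards models, and 1-year LTP ROC discrimination with the
operating point at the maximum of Youden's J.

## Worked example

The synthetic cohort generator produces paired phantom volumes whose masked
density drops and heterogeneity rises after "ablation", with response scores
and progression times drawn from a known proportional-hazards model:

```python
from deltarad import AblationDeltaModel, CohortTable
from deltarad.synthetic import extract_cohort_features, make_cohort, preset

cfg = preset("default", seed=7)           # 50 patients, 12x32x32 grids
synth = make_cohort(cfg)
features = extract_cohort_features(synth)
cohort = CohortTable(clinical=synth.clinical, features=features)
results = AblationDeltaModel(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Delta-radiomics ablation response analysis
==========================================================
patients: 50   complete ablation (Rvisu>=4): 60.0%   crude LTP incidence: 42.0%

Per-feature change (dP %, mean +/- SD over patients):
  mean                                      -277.7 +/-   130.3  p=0.0000 (wilcoxon_signed_rank)
  variance                                  +223.7 +/-   141.4  p=0.0000 (wilcoxon_signed_rank)
  zone_percentage                           +183.2 +/-   118.0  p=0.0000 (wilcoxon_signed_rank)
  cluster_prominence                       +1087.4 +/-   761.9  p=0.0000 (wilcoxon_signed_rank)
  contrast                                  +200.9 +/-   126.1  p=0.0000 (wilcoxon_signed_rank)
  ...
Spearman correlation with Rvisu:
  delta_contrast                         r=+0.868  p=0.0000
  delta_zone_percentage                  r=+0.829  p=0.0000
  ...
LTP group comparisons (Kaplan-Meier / log-rank):
  dcontrast_gt_30_5            n=37/13  incidence 24.3%/92.3%  logrank p=0.0000
  ...
12-month LTP discrimination (ROC):
  delta_contrast               AUC=0.830  sens=73.3%  spec=94.3%  (n=50)
  rvisu                        AUC=0.791  sens=80.0%  spec=77.1%  (n=50)
```

Reading the output: the masked mean density fell by ~278% of its baseline on
average (the baseline mean is close to zero HU, so the percent change is
large), texture contrast roughly tripled, and the per-patient contrast change
tracks the visual response score (Spearman r ≈ 0.87). Patients whose contrast
rose by more than 30.5% progressed far less often (24% vs 92%), and the
contrast change discriminates 1-year progression slightly better than the
visual score itself — the structure the generator was built to emulate.

The same analysis runs from files via the CLI:

```bash
deltarad simulate --preset tiny --seed 7 --out fixtures/
deltarad run-all --manifest fixtures/manifest.csv --out results/
```

which writes `features_long.csv`, `delta_report.csv`,
`correlation_table.csv`, `survival_tables.csv`, `roc_summary.csv` and a run
log with per-patient timings and flagged features.

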