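# Methods

This note documents the models, conventions, numerical choices and known
limitations of `deltarad`, in the order data flows through the package.

## Volumes, masks and resegmentation

Voxel arrays are `(z, y, x)` with 0-based indices, voxel-center geometry and
per-axis spacing in mm; physical position = origin + index × spacing. This
single stated convention keeps texture direction offsets unambiguous. Masks
are binary: a voxel belongs to the ROI iff its stored label is nonzero — no
partial-volume fractions.

Before any feature computation the ROI is resegmented to an HU analysis
range, default **[−1000, 400] HU in "remove" mode**: voxels outside the range
(air pockets, bone, metal streak) are dropped from the ROI rather than
clamped. CT display windows are not analysis ranges; the default range keeps
everything from aerated lung to dense soft tissue while excluding
non-tissue extremes, and it is exposed in the run configuration. A "clip"
mode is available.

No resampling is applied by default: the intended input is a same-session
pre/post pair acquired with identical parameters, where resampling only adds
interpolation noise. Optional isotropic resampling (linear image, nearest
mask) is provided.

A minimum analyzable ROI of **64 voxels** (configurable) is enforced by the
pipeline; texture statistics on smaller ROIs are dominated by their own
sampling noise.

### ROI geometry

Volume is voxel count × voxel volume; the maximum 3D diameter is the largest
pairwise distance between surface-voxel centers (exact Feret diameter; a
convex-hull reduction is used above 400 surface voxels purely for speed —
the hull contains the extremal pair). Elongation and flatness are
√(λ₂/λ₁) and √(λ₃/λ₁) of the ordered covariance eigenvalues of the voxel
centers. Sphericity is (36π V²)^⅓ / A with **A from a marching-cubes mesh**,
not from face counting: the face-counted area of a digitized ball converges
to 1.5× the true sphere area (the staircase artifact), which would rank a
ball as *less* spherical than a cube; the mesh area restores the intended
ordering and is the standard choice in radiomics harmonization work.

## Discretization

Matrix features require integer gray levels. The default is **fixed bin
width, 25 HU, anchored at the resegmentation lower bound (−1000 HU)**:
level = ⌊(x − low)/25⌋ + 1. CT is a calibrated absolute scale, and the
percent-change statistic compares the pre and post scans feature by
feature — a fixed, anchored width guarantees both scans are binned on the
same level scale, so a change in a matrix feature reflects a change in
tissue, not a change in binning. `fixed_bin_count` (equal-width bins over
the observed range) is provided for sensitivity analysis; it is
shift-invariant, which the test suite exploits.

## Texture features

All matrices are 3D. The 13 unique direction offsets (one per ± pair of the
26-neighborhood) are **merged into a single matrix before features are
computed**, rather than computing per-direction features and averaging: the
merged matrix is the simpler contract and is exactly reproducible by a naive
enumeration oracle, which the test suite runs on random ROIs. GLCM uses
distance 1 (voxels) and symmetric counting; runs are broken by out-of-mask
voxels; zones are 26-connected components of equal level; the NGTDM
neighborhood is the in-mask part of the 26-neighborhood.

Conventions that matter when comparing against other implementations:

* entropies are base-2 (bits), with 0·log 0 := 0;
* kurtosis is **non-excess** (m₄/m₂²; a Gaussian scores 3);
* variance and the other moments divide by N (population style);
* the robust mean absolute deviation is the MAD about the mean of the
  values restricted to the closed [P10, P90] range;
* global features are computed on raw (resegmented) HU values —
  discretization affects only the matrix features;
* a constant ROI has zero gray-level variance; its GLCM correlation is
  defined as 1 (perfectly predictable texture) and flagged, and NGTDM
  coarseness uses 1/(ε + Σpᵢsᵢ) with ε = 10⁻¹², so it stays finite;
* features that cannot be computed are flagged-missing (NaN plus a reason),
  never silently zero.

NGTDM features are computed but excluded from the default ΔP report: the
19-feature report covers the global/regional/local blocks, and the
neighborhood-difference block is an optional extra (`include_ngtdm`).

## The percent-change statistic

ΔP = (P2 − P1)/P1 × 100, signed. Two decisions guard its known
pathologies:

* **near-zero baselines**: with lung lesions the baseline mean HU can sit
  near zero, making the ratio explode. A per-feature floor of
  10⁻⁶ × (cohort IQR of P1) marks such patients' ΔP undefined; they are
  excluded per feature with the count reported.
* **cohort aggregation is mean-of-ratios**: the cohort summary is the mean
  ± SD of the per-patient ratios, *not* the ratio of cohort means. The two
  differ badly when baselines cross zero (with cohort means 30.342 → −60.893
  the ratio of means is −300.7% while a per-patient aggregate can be
  −321.4%); conflating them is a real reporting hazard this package avoids
  by construction.

## Response scoring

The rubric maps an observer's reading to 5 (no enhancement, shrunk),
4 (no enhancement, stable/slightly enlarged), 3 (residual enhancement
< 50% of baseline), 2 (residual ≥ 50% or a new enhancing zone). "No
enhancement but frankly enlarged" has no defined score and is treated as an
input error rather than guessed. Rvisu is the arithmetic mean of the three
observers' integer scores; mean ≥ 4 defines complete ablation. No
inter-observer agreement statistics are computed.

## Statistical analysis

* Paired P2-vs-P1 tests are gated by a Shapiro–Wilk test on the paired
  differences at α = 0.05: normal → paired t, otherwise Wilcoxon signed-rank
  (zeros dropped; exact p for small untied samples, normal approximation
  with continuity correction otherwise). Two-sided throughout. At least 6
  pairs are required; all-zero differences skip the test with a flag.
* Correlations with Rvisu are Spearman with average-rank ties and the
  two-sided t-approximation p; baseline diameter and volume are correlated
  with Rvisu the same way. At least 5 patients with defined values are
  required; constant inputs are flagged.
* Survival: Kaplan–Meier product-limit curves (events before censorings at
  ties), the median read as the earliest time with S ≤ 0.5 (undefined if
  never reached); two-group log-rank tests; Cox partial likelihood with
  Efron tie handling (follow-up is in months — ties are certain) and Wald
  CIs/p-values, delegated to lifelines. Multivariate models with fewer than
  10 events are flagged, as are constant covariates and suspected
  separation. Because ΔP features are strongly collinear, multivariate
  models are **separate-entry**: one model per image feature, always
  accompanied by the visual-score indicator. Clinical reports sometimes
  label Cox output "odds ratios"; the values here are hazard ratios and are
  labeled as such.
* Dichotomization presets: Δcontrast% > 30.5 and Δzone-percentage% > 21.5
  (strict), Rvisu ≥ 3, diameter ≥ 3.6 cm, volume ≥ 4.1 cm³, age ≥ 67
  (non-strict). Undefined values are excluded with counts.
* 1-year ROC: the label is "progression within 12.0 months"; patients
  censored event-free before the horizon are not evaluable and are excluded
  (with the count reported) — there is no principled way to label them
  without a competing-risks model, which is out of scope. AUC is the
  trapezoidal/midrank concordance; the reported operating point maximizes
  Youden's J (sensitivity + specificity − 1). Retreatment before progression
  censors the patient on the treatment day.

## The synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
with ground truth stored separately from anything the analysis reads.

* **Phantom**: a sphere/ellipsoid/lobulated lesion (default radius 14 mm on
  a 12×32×32 grid at 5×1×1 mm — thick-slice chest CT) of baseline mean
  30 HU plus a correlated Gaussian texture field (white noise smoothed with
  a 1-voxel Gaussian kernel, scaled to SD 40 HU), on a −800 HU lung
  background. The post-ablation twin keeps the geometry (acute ablation
  does not change tumor volume) and reuses the same field with the mean
  shifted down and the amplitude multiplied — so a zero-effect
  configuration is voxel-identical to the pre volume and every change is
  attributable to the configured effect. The smoothed-field amplitude is
  the simplest knob that moves GLCM contrast monotonically, which the test
  suite verifies.
* **Response classes**: visual scores are drawn with fractions
  0.40/0.32/0.18/0.10 for scores 5/4/3/2 (the 20/16/9/5 split of a
  published 50-patient series; the five 2-scores comprise three residual
  and two new-zone lesions). Class effects (mean drop, amplitude
  multiplier) are (110, 2.1), (90, 1.85), (45, 1.12), (15, 1.02) — strong
  responders change a lot, weak responders barely — with ±15%/±8%
  patient-level jitter and ±(0.75–1.05) jitter on lesion radius. These
  effect sizes are not estimated from any patient data; they are chosen so
  the classes are clearly separated at the analysis's preset thresholds,
  which is what makes recovery testable.
* **Observers**: each of three observers reports the true score ±1 with
  probability 0.1 per side (clipped to [2, 5]), giving realistic
  non-integer Rvisu means.
* **Progression**: the true high-effect group is "amplitude multiplier
  ≥ 1.5" (classes 5/4). Event times are exponential; the low-effect group's
  hazard is ln 2 / 10 per month (median 10 months) and the high-effect
  group's hazard is lower by a factor of 5.61 (log-HR = log 5.61, matching
  the hazard ratio the analysis should recover). Censoring is uniform on
  12–28 months (the follow-up window), optionally plus an independent
  exponential censoring stream. With 50 patients this yields roughly 20–22
  events.
* Everything is deterministic given the seed; per-patient substreams keep
  patients independent; exports (NIfTI + manifest CSV + ground-truth JSON)
  are byte-identical across re-runs with the same seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: anatomy (airways, vessels, pleural contact),
partial-volume and reconstruction-kernel effects, registration error between
the two scans, ablation-zone gas and needle artifacts, observer bias that
correlates with lesion size, and any dependence of progression hazard on
baseline geometry. Shape-invariant features (e.g. kurtosis) do not change
between the paired phantoms at all, because the post field is a scaled copy
of the pre field; their ΔP is exactly zero by construction.

## Problem sizes and numerical tolerances

Brute-force oracle equivalence is checked to 1e-9 on 100 random ROIs up to
6×6×6 with ≤ 5 levels. Statistical recovery uses 100 simulated cohorts of
n = 500 per hazard ratio in {1, 2, 5.61} (median log-HR deviation < 0.05 per
HR; 95% CI coverage pooled over the 300 cohorts, since a 100-rep binomial
cannot resolve a [0.92, 0.98] band), 1000 log-rank replicates at 50 per
group for the type-I error, 500 null-ROC replicates at n = 200, and one
end-to-end 500-patient synthetic cohort on 8×16×16 grids. These sizes keep
the default suite comfortably reproducible on a single CPU while leaving
the Monte-Carlo error well inside each assertion's band.

## Known limitations

* Feature definitions follow the conventions stated above; other radiomics
  software (different aggregation, excess kurtosis, natural-log entropy,
  re-binned GLRLM levels) will produce systematically different values.
* ΔP is undefined for near-zero baselines by design; cohorts whose baseline
  feature distributions straddle zero will report exclusions.
* The 1-year ROC excludes early-censored patients rather than modeling
  them; with heavy early censoring the evaluable subset may be biased.
* No competing-risks modeling, no time-dependent covariates, no
  overall-survival endpoint, no automatic segmentation, no DICOM-RT
  structure sets, no 2D slice-wise or filtered-image (wavelet) features.
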