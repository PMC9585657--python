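# Methods

`gliotex` implements a slice-based MR texture-radiomics pipeline for binary
classification of high-grade glioma into IDH-mutant and IDH-wild-type
subgroups, together with a synthetic textured-phantom cohort generator that
stands in for private hospital imaging data. This note records the model,
the conventions chosen where the underlying method leaves them open, and
what the synthetic experiments do and do not demonstrate.

## Pipeline

For each patient, two co-registered MR-like channels (contrast-enhanced T1,
`T1C`, and T2-weighted, `T2`) share one binary tumor ROI mask. Analysis is
per axial slice:

1. **Multi-scale LoG filtering.** Each slice is band-passed with negated,
   scale-normalized Laplacian-of-Gaussian kernels at spatial scale filter
   (SSF) levels 2–6 mm; SSF 0 is the unfiltered image. The whole slice is
   filtered before the mask is applied, so the ROI pool is free of
   mask-edge ringing; borders use mirror extension, and the discrete kernel
   is mean-subtracted so it is exactly zero-sum.
2. **First-order features (36).** Mean, SD, mean of positive pixels (MPP),
   entropy, skewness and kurtosis of the in-ROI pixel pool at each of the
   6 SSF levels.
3. **GLCM features (40).** On the unfiltered image only, in-ROI pixels are
   quantized to Ng = 64 equal-width gray levels over the in-ROI min–max;
   symmetric co-occurrence matrices are accumulated at pixel distances 1
   and 4 along the four in-plane directions (0,1), (1,0), (1,1), (1,−1)
   scaled by the distance, counting only pairs with both pixels inside the
   ROI. Twenty features per distance are computed per direction and
   averaged over the directions with at least one valid pair.
4. **Shape features (6).** Perimeter, area, elongation, sphericity, long
   and short axis of the slice ROI, in physical units.
5. **Dataset assembly.** Either every tumor-bearing slice is one sample
   ("single-slice multiple sampling", the augmentation mode) or per-patient
   feature vectors are averaged across slices ("multislice", one sample per
   patient).
6. **Modeling.** Features are z-scored with training-fold parameters,
   selected by L1-penalized (LASSO) logistic regression with the penalty
   chosen at minimum mean 10-fold cross-validated binomial deviance, and
   classified by a polynomial-kernel SVM (degree 1/2/3 = linear /
   quadratic / cubic). Evaluation pools out-of-fold decision scores from a
   stratified, patient-grouped 10-fold cross-validation (or a stratified
   hold-out split): rank-based AUC reported with either class designated
   positive, plus a confusion matrix at the decision-score sign and its
   derived rates (sensitivity, specificity, PPV, NPV, FNR, accuracy).

The full vector is 82 features per sequence — 36 first-order + 20 GLCM at
distance 1 + 20 at distance 4 + 6 shape — and 164 when the two sequences
are combined. Names follow the `STAT_SSF_SEQ` / `GLCM{d}_{name}_SEQ` /
`SHAPE_{name}_SEQ` grammar (e.g. `KURTOSIS_2_T1C`, `GLCM1_sumEntropy_T2`).

## Conventions chosen where the method is underdetermined

* **SSF → Gaussian width.** The SSF value is documented only as the width
  (radius) in mm of the structures a band highlights. We map
  `sigma_mm = ssf / (2 * sqrt(2))`, which makes the LoG kernel's
  zero-crossing circle exactly `ssf` mm in diameter; with the standard
  scale normalization (response x sigma^2) this places the peak center
  response to a bright disk of diameter d mm exactly at SSF d, verified
  numerically for all five scales. The simpler `sigma = ssf/2` mapping
  fails that matched-scale property for SSF ≥ 4 (the analytic optimum for
  a disk of radius r is `sigma = r/sqrt(2)`). The ratio is exposed as the
  `sigma_per_ssf` knob.
* **Filter sign.** Responses are negated so bright blobs give positive
  values, making MPP behave as a bright-structure statistic.
* **Quantization.** Fixed bin number (Ng = 64) over the in-ROI min–max per
  slice — the common choice for MR's arbitrary intensity units; it makes
  every GLCM feature invariant to adding a constant to the image.
  Configurable.
* **First-order conventions.** SD and skewness use population moments (the
  ROI is the whole population of tumor pixels); kurtosis is excess
  (normal → 0); entropy is Shannon entropy in bits of a 64-bin histogram
  over the pool min–max, mirroring the GLCM discretization. MPP with no
  positive pixels is recorded as 0 with a logged warning.
* **Degenerate GLCMs.** A zero-variance (single-cell) matrix has
  correlation reported as 0; entropies use `0*log 0 = 0`.
* **Shape axes.** Long/short axis are the ellipse-equivalent diameters
  `4*sqrt(eigenvalue)` of the second central moment matrix of the in-mask
  pixel centers, with the per-pixel square extent (`s^2/12` per axis)
  added so one-pixel-wide regions keep a nonzero width. The perimeter is
  the length of the sub-pixel iso-contour of the mask after one 3-point
  moving-average smoothing pass of the traced polygon, which removes the
  marching-squares staircase bias (a digital disk of radius 20 px then has
  sphericity 0.99 rather than 0.95). Sphericity is the 2D isoperimetric
  ratio `2*sqrt(pi*area)/perimeter`.
* **Minimum ROI size.** Slices with fewer than 16 in-ROI pixels are
  skipped (GLCMs and moments are unstable below this); slices whose ROI
  admits no pixel pair at a required distance in any direction are likewise
  skipped. Both are logged.
* **Multislice aggregation.** Unweighted per-feature mean across a
  patient's slices (area-weighted mean available), since the texture tool
  is inherently 2D and patient-level analysis has one sample per patient.
* **Grouping.** Slice-level splits keep all slices of a patient on one
  side of every split — a deliberate strengthening against within-patient
  leakage; it can be toggled off to mimic instance-level splitting.
* **LASSO.** glmnet-style parameterization: objective
  `(1/n) Σ deviance + λ‖w‖₁`, descending log-spaced 40-point grid from
  `λ_max = max|Xᵀ(y − ȳ)|/n` down to `10⁻³ λ_max`, penalty chosen at
  minimum mean CV deviance ("lambda.min"). Selection is nested inside each
  outer training fold by default; `global_selection` performs one global
  selection before the CV loop instead (the simpler historical design,
  kept for fidelity comparisons).
* **SVM.** Polynomial kernels with unit scale, zero offset, box constraint
  C = 1 on pre-standardized features; the confusion matrix uses the
  decision-score sign (a single operating point, no threshold tuning).
* **AUC.** Rank-based (Mann–Whitney) with half-credit for ties; for any
  binary problem the AUC is identical whichever class is designated
  positive.

## The phantom generator

Each synthetic patient is an ellipsoidal tumor (semi-axes drawn from
8–16 mm, capped at 45% of each axis extent) placed in a 20 x 64 x 64-voxel
volume at 1 mm isotropic spacing, on a smooth background blob standing in
for brain parenchyma. Within the mask, intensities are a class-conditional
Gaussian random field: white noise convolved with a Gaussian kernel whose
sigma is the class's correlation length, passed through a monotone
sinh–arcsinh transform inducing the class's histogram skew, re-standardized
to the configured tumor mean (120) and amplitude (1), plus additive white
noise (SD 0.2). The two channels share the underlying white noise with
correlation 0.5, so they are related but not redundant. Default cohort
conditions are 100 patients with 17 positive ("mutant") cases; the default
class textures differ in correlation length (1 mm wild vs 4 mm mutant) and
skew (0 vs 0.5) at equal amplitude.

What the phantom emulates: class-conditional differences in spatial
correlation, contrast and histogram shape; per-slice masks over multiple
slices per patient; coupled but distinct channels; the study's 83:17 class
imbalance. What it does not: brain anatomy, MR physics (bias fields,
TR/TE-dependent contrast), multicentric or infiltrative tumor geometry,
scanner heterogeneity. Passing phantom experiments therefore demonstrates
that the pipeline recovers texture-statistical class structure without
leakage — not that any particular clinical accuracy is attainable on real
cohorts.

A caution from the scaled-down experiments: the class correlation length
must stay well below the tumor diameter. When it approaches tumor size the
within-ROI field degenerates toward a constant offset and the texture
contrast between classes collapses, so effect-size sweeps on small phantoms
use correlation gaps small relative to the tumor radius.

## Problem sizes and numerical choices

Simulation-backed checks use these sizes, chosen to make the full suite a
desk-scale run: the null-calibration experiment uses 20 replicate cohorts
at the default geometry (100 patients) with identical class textures and
asserts the replicate-mean pooled CV AUC lies in [0.35, 0.65] — the
per-replicate null AUC with 17 positives has a standard deviation of about
0.08, so the mean over 20 replicates (SE ≈ 0.02) is the meaningful
no-leakage statistic while individual replicates can legitimately stray
near the band edges. Signal recovery uses one seeded default cohort
(1 mm vs 4 mm correlation length) and requires pooled CV AUC of the
combined-sequence quadratic model above 0.85. Selection sanity uses 40
replicates of one informative feature (2 SD effect) among 50 noise
features at n = 200. Unit-level property checks (effect-size monotonicity,
isotropy, replicate means) run on compact phantoms (10 x 32 x 32 to
10 x 40 x 40 voxels, 12–24 patients).

Numerical tolerances: GLCM oracle equivalence to 1e-10 against brute-force
pair enumeration; filter linearity to 1e-9 relative; feature-table CSV
round-trips preserve at least 12 significant digits. All randomness fans
out from a single pipeline seed (phantom generation, fold assignment,
penalty CV), and a fixed seed reproduces byte-identical feature tables.

## Known limitations

* GLCM and shape families only; no run-length, size-zone, NGTDM or wavelet
  features, and no 3D texture matrices.
* No probability calibration and no class-weighted SVM: with an 83:17
  imbalance the sign-threshold operating point favors the majority class,
  which is part of the behavior the package reproduces.
* NIfTI input only; sequences are assumed co-registered with one shared
  mask (per-sequence masks are accepted but not resampled).
* Hold-out validation on 100 patients leaves 1–3 positive test cases and
  is reported but statistically fragile, as expected at this cohort size.
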