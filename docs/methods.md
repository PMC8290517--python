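# Methods

`gliomics` implements an end-to-end radiomic classification pipeline for
preoperative prediction of 1p/19q codeletion status in WHO grade II
gliomas, together with a synthetic phantom cohort generator that stands in
for patient images. This note records the models, the numerical choices,
and what the synthetic experiments do and do not demonstrate.

## The classification problem

1p/19q codeletion (combined loss of chromosome arms 1p and 19q) defines,
together with IDH mutation, the oligodendroglioma subtype of low-grade
glioma and predicts better prognosis. The pipeline predicts this binary
label (codeletion = 1) from quantitative features of three preoperative MRI
sequences — T1-weighted, T2-weighted, and contrast-enhanced T1-weighted —
restricted to a manually segmented tumor mask, plus age and sex.

## Phantom cohort generator

Patient images of this kind are not publicly deposited, so the package
generates phantoms that preserve the study structure the pipeline is built
for:

- **Cohort composition.** 65 codeleted and 92 non-codeleted subjects by
  default; 16 of the non-codeleted are flagged IDH-wildtype. Codeletion
  implies IDH-mutant (the WHO 2016 oligodendroglioma definition) and the
  generator enforces this invariant.
- **Clinical covariates.** Age ~ N(41.6, 10.4²) years drawn identically
  for both classes (age carries no class signal by construction); sex is
  Bernoulli with the cohort's female fraction (73/157).
- **Tumor geometry.** Random-axis ellipsoids (axis ratios uniform in
  [0.7, 1.3]) whose volumes follow a truncated normal with mean 59.87 and
  SD 52.74 cm³, truncated below at 2 cm³ and above at what fits in the
  image grid with a margin. At the default 64³ grid with 1-mm voxels the
  upper truncation is ~100 cm³, so realized mean volume sits below the
  nominal mean; this is the stated law clipped by geometry, not a new law.
  One volume law serves both classes (no per-class volume statistics are
  modeled).
- **Texture model.** Tumor interiors are filled with a standardized
  Gaussian random field (white noise smoothed with a Gaussian kernel).
  The two classes share a base correlation length of 2 mm; a single
  effect-size knob `homogeneity_gap` (default 1.0, dimensionless) scales
  the class contrast: codeleted tumors get correlation length
  2/(1 + gap/2) mm plus a heavy-tail transform `g + 0.15·gap·g³`
  (restandardized), non-codeleted get 2·(1 + gap/2) mm. At gap 0 the two
  laws coincide exactly. Shorter correlation length and heavier gray-level
  tails make codeleted tumors *less homogeneous*, which is the direction
  of the class difference reported for oligodendrogliomas; downstream,
  the GLCM features Informational Measure of Correlation 2 and Cluster
  Tendency come out lower in the codeleted class, monotonically in the
  knob. (Plain GLCM homogeneity is *not* a clean readout here: the heavy
  tail widens the ROI intensity range, and fixed-bin-count discretization
  then compresses the core into fewer levels.)
- **Channels.** The three sequences share one spatial field with
  channel-specific gain and offset (T2 bright, T1 dark, intermediate
  enhancement) plus independent voxel noise (SD 0.15), over a smooth
  nonzero "brain" ellipsoid background. Multi-sequence features are
  therefore correlated but not identical, mimicking real multi-sequence
  redundancy. Channels are emitted voxel-aligned; cross-sequence
  registration is treated as a precondition, not a pipeline step.

**What the phantoms do not emulate:** MRI physics (bias fields, k-space
artifacts, partial volume), multi-site scanner variation, infiltrative
(non-ellipsoidal) tumor margins, anatomically realistic brain background,
or any imaging phenotype of IDH status (wildtype subjects are flagged but
drawn from the non-codeleted texture law). Passing tests on phantoms
demonstrates that the pipeline is correct, leakage-free, and able to
recover a texture-homogeneity class difference of the modeled kind — not
that it attains any particular accuracy on patients.

A tabular twin, `planted_feature_table`, draws feature matrices with a
known number of discriminative columns (default 6) among noise columns;
it is used wherever ground truth about *which* features carry signal must
be exact (selection calibration, consensus recovery).

## Preprocessing

Volumes and masks are resliced to 1.0-mm isotropic grids (trilinear for
intensities, nearest-neighbor for masks, preserving physical extent to
within a voxel), then each volume is z-scored over its nonzero (brain)
voxels — not tumor-only — so tumor intensities are comparable across
subjects and sequences. The z-score uses the population SD (divide by n),
fixed for bit-reproducibility; at brain scale the sample/population
distinction is immaterial. Order of operations: resample → normalize →
extract.

## Feature catalogue (431 per sequence, 1,293 per subject)

- **Group 1 — 14 first-order statistics** of ROI intensities: energy,
  entropy, kurtosis (Pearson, m4/m2²), maximum, mean, mean absolute
  deviation, median, minimum, range, RMS, skewness, SD (population),
  uniformity, variance. Entropy/uniformity use the same fixed-bin-count
  histogram as the texture features. Zero-variance ROIs return 0 for
  skewness/kurtosis with a warning rather than NaN.
- **Group 2 — 8 shape features**: volume (voxel count × voxel volume),
  surface area, surface-to-volume ratio, compactness 1 and 2, spherical
  disproportion, sphericity, maximum 3D diameter (largest pairwise
  boundary-voxel distance, computed on the convex hull). The surface mesh
  is marching cubes on a 2× trilinearly upsampled, σ = 0.7-fine-voxel
  smoothed occupancy field: meshing the raw binary lattice chamfers flat
  faces (a 10-voxel cube came out 6% low) and facets curved ones (a
  radius-10 ball 9% high); the calibrated field reproduces the cube's
  closed-form sphericity (π/6)^(1/3) within 0.03 and brings tumor-scale
  balls to ~0.95. Fragmented masks use their largest connected component.
- **Group 3 — 33 texture features**: 22 from the gray-level co-occurrence
  matrix and 11 from the gray-level run-length matrix. Intensities are
  discretized by fixed bin count (default 32 levels) over the ROI min–max,
  making texture features invariant to affine intensity shifts. GLCM:
  co-occurrences over all 13 unique distance-1 3D directions, symmetrized
  and summed into one matrix before feature computation. GLRLM: run-length
  matrices per direction, features averaged over the 13 directions. Three
  GLCM names that collide with first-order names carry a "GLCM" prefix
  (GLCM Energy/Entropy/Variance) so all 431 names are unique. Texture
  features of a single-level ROI return their analytic degenerate values
  (contrast 0, energy 1, maximum probability 1, IMC 0), never NaN.
- **Group 4 — 376 wavelet features**: a single-level undecimated separable
  3D wavelet transform (coiflet-1 by default, configurable) yields 8
  sub-bands LLL…HHH, each at full image shape so the original mask applies
  unchanged; the 14 first-order + 33 texture features are recomputed on
  each band: 8 × 47 = 376. Band-index suffixes `_1` … `_8` follow the
  order LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH (filters applied along axes
  0, 1, 2); this convention is the package's own — no claim is made that
  it matches any particular published suffix numbering. Boundary handling
  is mirror reflection; axes shorter than the filter are reflect-padded
  with a warning.

Feature names follow `<SEQ>_Group <k>_<Feature Name>[_<band>]` with SEQ in
{T1WI, T2WI, CE-T1WI}. Age and a sex indicator (female = 1) complete the
1,295 predictor columns. Because neighbor-pair lists and run-scanning
orders depend only on mask geometry, they are computed once per subject
and reused across all 27 filtered volumes, which keeps full-cohort
extraction at 64³ in the minutes range on one CPU.

## Feature selection: elastic net

Within each outer training set, predictors are z-scored on training
statistics and screened by an elastic net (least-squares loss on the 0/1
labels by default — the classical formulation for this analysis — with a
logistic-deviance family available via config). The mixing parameter α
runs over 0–1 in steps of 0.1; for each α a 30-point descending λ path is
scored by stratified 10-fold CV (λ_max = max|xᵀy|/(n·max(α, 10⁻³)), three
decades down). The intercept-only (null) model competes explicitly as the
λ→∞ limit of every path: per-fold λ_max can exceed the global one, so no
finite grid point attains the exact null loss.

The default selection rule is a **one-standard-error parsimony rule over
the joint (α, λ) grid**: among all candidates (null model included) whose
mean CV loss is within one SE of the global minimum, take the most
parsimonious — the null model if it qualifies, else the largest α with any
qualifying λ, at its largest qualifying λ. A plain CV-minimum rule is
available (`selection_rule="min"`). The parsimony rule is what makes the
false-selection calibration hold: on signal-free data the CV minimum is
the minimum of ~300 jittery curve points and is routinely won by the
ridge corner, which would "select" every feature; under the parsimony
rule signal-free data collapse to the empty selection. α = 0 exactly is a
documented degenerate corner: ridge never zeroes coefficients, so if it
wins, all features are returned with a warning and a degenerate flag.

## Classifier: RBF-SVM with Platt calibration

The SVM uses the RBF kernel K(x, x′) = exp(−‖x − x′‖²/s²) (kernel scale
s; sklearn γ = 1/s²) and box constraint C. Grids are log-spaced, C over
[10^⅓, 10³] (9 points) and s over [10, 10^(7/3)] (5 points), bracketing
the hyperparameter ranges such models realize on this problem scale. The
pair minimizing inner stratified 10-fold misclassification loss wins; ties
break toward smaller C, then larger s (stronger regularization). Posterior
probabilities come from a Platt sigmoid p = 1/(1 + exp(A·f + B)) fitted
with target smoothing on *inner-CV out-of-fold* decision values at the
chosen pair — never on training decision values, which would overstate
confidence. An empty selected-feature set trains a prior-only classifier
emitting the training prevalence, with a warning.

## Nested cross-validation

Outer 10-fold stratified splits (stratification keeps per-fold class
counts within one subject of balance; at 41% prevalence unstratified folds
risk near-empty classes; an unstratified mode exists). Per outer fold:
z-score on the 9 training folds (all predictor columns uniformly,
including age and sex), select, tune, fit, calibrate — all on training
rows — then score the held-out fold once. Selection and tuning run
sequentially (select → tune). Fold seeds derive deterministically from the
plan seed; feature matrices are converted to a canonical contiguous memory
layout on entry because summation order follows strides and the leakage
test demands bit-identical refits. Features selected in all 10 outer folds
form the consensus set, reported with raw Welch t-test p-values per
feature (no multiplicity correction, matching per-feature reporting
practice). A subgroup run re-executes the identical pipeline on a flagged
subset (typically IDH-mutant), and the misclassification count among the
excluded subjects is reported separately.

## Evaluation battery

All metrics are computed on pooled out-of-fold posteriors — the only
reading that yields a single integer confusion matrix for the whole
cohort. Operating threshold 0.5 (the canonical posterior cut; the
published metric set is arithmetically self-consistent with integer
confusion counts at this threshold, which the acceptance suite verifies).
AUC is trapezoidal over all thresholds, equal to the midrank Mann-Whitney
statistic; the precision-recall analysis reports F1 at the operating
point. Confidence intervals are percentile bootstrap, 1000 resamples,
stratified by class (every resample keeps both classes). Point-biserial
correlation is Pearson against the 0/1 labels with the t-based p-value
(n − 2 df). The posterior group comparison is a Welch t-test by default
(pooled-variance optional). Undefined corners are explicit: precision with
no positive predictions is reported as 0 with a warning; one-class inputs
raise.

## Null behavior of nested CV

Under the null (no class signal), nested CV with embedded selection is
*pessimistically* biased: fold models fit noise and anti-correlate with
their held-out data, and pooled null AUCs center slightly below 0.5
(mean ≈ 0.46 at n = 100 in the test configuration) with spread wider than
the raw Mann-Whitney null SD. The null calibration test therefore checks
that the mean AUC over 20 seeds is centered at chance within a single-run
null SD and that its upper confidence bound shows no *optimistic* shift —
the signature leakage would produce. A pessimistic null is the honest
behavior of this design, not an error.

## Problem sizes

Tests and the acceptance script run the full pipeline at the study's
cohort size (157 subjects) on 64³ phantoms, the package's desk-scale
default for a single CPU: cohort generation and feature extraction take a
few minutes, the nested CV on the 1,295-column table a few more. Unit
tests use smaller grids (24³–48³) and the tabular twin. Image shape,
discretization levels, wavelet family, grids and rules are all
configurable upward.

## Known limitations

- The feature catalogue follows the classical 431-feature extraction
  lineage; it is not IBSI-certified (conventions overlap but are not
  certified equivalents).
- The Platt fit is unconstrained; on adversarially degenerate calibration
  data the slope could invert (not observed under the tested conditions).
- The elastic-net CV curves use a fixed 30-point λ path; pathological
  designs could place the optimum between grid points.
- Phantom realism limits are listed above; in particular, absolute
  performance numbers on phantoms depend directly on the chosen
  `homogeneity_gap` and transfer to no patient population.
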