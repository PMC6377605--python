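# Methods

`rpvkit` implements a 3D CT radiomics engine for segmented tumor volumes,
the four-feature Radiomic Prognostic Vector (RPV) for high-grade serous
ovarian cancer, the survival-signature discovery pipeline that produces
such scores, and the reliability analyses that audit them. This note
records the models, conventions and numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Imaging model and geometry

Volumes are 3D grids of Hounsfield Units indexed `(x, y, z)` with `z` the
cranio-caudal axis; all geometry is in millimetres. DICOM series are
rescaled to HU via RescaleSlope/Intercept and require consistent
orientation, in-plane spacing, and inter-slice gaps (variation above 1%
is a geometry error). Masks are binarized (`> 0`) and must match their
volume's shape exactly and spacing within 1e-3 mm.

**No resampling by default.** Abdominal CT is acquired with anisotropic
voxels (slice thickness commonly 1-10 mm) and the analysis operates on
native geometry; `resample_isotropic` (trilinear image, nearest-neighbor
mask) is an explicit opt-in.

## Discretization

Texture families operate on gray levels obtained by fixed-bin-width
quantization: `level(v) = floor((I(v) - anchor)/b) + 1` with `b = 25` HU
and the anchor at the masked minimum, so bins are half-open
`[edge, edge + b)` and a value on an upper edge belongs to the higher
bin. Min-anchoring makes the rule applicable unchanged to wavelet
sub-bands, whose values are not HU-offset; sub-band features reuse the
same bin width of 25 (the `25HUgl` tag in feature names refers to this
quantization step). Adding a constant to all masked intensities leaves
the levels unchanged, and `Ng = floor((max - min)/b) + 1`.

## Wavelet sub-bands

A single-level *undecimated* separable transform with the coiflet-1
filter pair produces 8 sub-bands named by the filter applied along each
axis in `(x, y, z)` order (`HLL` = high-pass along x, low-pass along y
and z). Undecimated filtering keeps every sub-band voxel-aligned with
the original segmentation, which is what makes masked sub-band
statistics such as the median of `LHH` well defined; boundary handling
is symmetric (mirror) extension. A decimated transform and other
boundary rules are deliberately not offered — sub-band/mask alignment is
a correctness requirement here, not a tuning choice.

## Feature registry (657 descriptors)

Names follow `FAMILY_stat[_band][_25HUgl]`: the band token is omitted on
the original image and the tag marks statistics computed on quantized
levels. The registry enumerates

* 9 shape/size features (mask only);
* per image (original + 8 sub-bands = 9 images), 72 features:
  22 first-order, 26 co-occurrence (GLCM), 16 run-length (GLRLM),
  5 neighborhood gray-tone difference (NGTDM), 3 fractal;

giving 9 + 9 x 72 = 657. The registry object defines count and order and
is the source of truth; extraction fails loudly on any non-finite value,
naming the feature.

Conventions that matter:

* **GLCM/GLRLM aggregation** — distance-1 co-occurrences and runs over
  the 13 unique 3D directions, aggregated by *matrix summation* before
  normalization. Summation is the run-conserving convention:
  `sum_ij r(i,j) * j = 13 * Nv` holds exactly on every extraction.
* **NGTDM** — 26-connected neighborhoods restricted to the mask; voxels
  with no masked neighbor are excluded from `Nv`. Contrast is
  `[1/(Ngp(Ngp-1)) sum_ij p_i p_j (i-j)^2] * [sum_i s(i) / Nv]` and 0
  when a single level occupies the region.
* **Degenerate regions** — single-level regions take their continuity
  limits (entropy 0, uniformity 1, contrasts 0, correlation 0, MCC 1,
  coarseness capped at 1e6) so NaN never propagates into a score.
* **Surface area** — marching cubes on the binary mask lightly smoothed
  with a Gaussian of 0.8 voxel; meshing the raw binary grid inflates the
  area of a digital sphere by ~9%, and the smoothed mesh brings
  sphericity of a radius-20 sphere to 0.996 while never exceeding 1.
  Structures too small to survive smoothing fall back to the binary
  mesh. The maximum 3D diameter is the largest pairwise distance between
  boundary-voxel centers, computed on their convex hull.
* **Fractal dimension** — for each occupied threshold `t`, the set
  `{level >= t}` inside the mask bounding box is box-counted over dyadic
  sizes (at least 3 sizes required, otherwise flagged) and the dimension
  is the least-squares slope of `log N` vs `log(1/eps)`; `FD_max`,
  `FD_mean`, `FD_sd` summarize the thresholds. Per-threshold max is the
  reading under which a "maximal fractal dimension" feature is well
  defined.
* **First-order** — population (n-denominator) moments; median of an
  even-count sample is the midpoint of the middle two; entropy and
  uniformity are computed on the 25-unit histogram.

## RPV

`RPV = -0.0876 * FD_max_25HUgl + 0.0869 * GLRLM_SRLGLE_LLL_25HUgl
+ 0.165 * NGTDM_Contra_HLL_25HUgl + 0.250 * FOS_Imedian_LHH`, with risk
groups low `(-inf, 0.0950)`, medium `[0.0950, 0.658)`, high
`[0.658, inf)`. The printed group ranges are closed-looking; the
half-open convention (upper boundary belongs to the higher group) is a
measure-zero determinism choice, documented and tested. Bilateral
patients keep the higher-RPV tumor; exact ties break on sorted tumor id.
Cohort standardization (used for validation cohorts, mirroring the
original procedure's ordering: discovery scores on raw features,
validation features scaled and centered first) is `(x - mean)/sd` with
the n-1 sd; constant columns pass through as 0 with a warning.

## Signature discovery

* **Screen** — per feature, a Cox model containing that feature plus the
  adjusters (default stage, slice thickness, residual disease; pass an
  empty tuple for marginal HRs), Efron ties, Wald p for the feature's
  coefficient, Benjamini-Hochberg across features with strict `q < 0.05`
  pass flags. Non-converging features are flagged with `p = 1` rather
  than dropped. Both bilateral tumors enter as rows at this stage.
* **LASSO-Cox** — L1-penalized path (50 penalties, min ratio 0.01);
  the penalty is chosen at the minimum mean 10-fold cross-validated
  deviance, with the Verweij-van Houwelingen definition
  `dev_k = -2 [pl(beta_-k; all) - pl(beta_-k; train_-k)]` and the
  Breslow partial likelihood (simulated survival times are continuous,
  so tie handling is immaterial there). Folds are stratified by event
  status so no fold is event-free, and seeded; an empty selection at the
  optimum is returned as a valid empty model with a warning.
* **Risk groups** — 1D k-means (10 seeded restarts), clusters ordered by
  center, boundaries at midpoints between adjacent clusters' extreme
  members; assignment is monotone in score because 1D k-means clusters
  are intervals.
* **Evaluation** — uni-/multivariable Cox of the continuous score
  (lifelines), C-index of the risk ordering, log-rank across groups
  (skipped with a warning when a group is empty), Kaplan-Meier curves
  with at-risk counts.

### Sample size

The log-rank design uses Schoenfeld's event count
`d = (z_{1-alpha/2} + z_power)^2 / (p_e (1 - p_e) ln^2 HR)` where `p_e`
is the *expected proportion of events* in the high-risk group, and
converts events to cases with the overall event probability under
exponential survival at the group medians and administrative censoring
uniform on `(0, follow_up)`; the result is rounded up. Under the
published design (HR 2.78, alpha 0.05, power 0.75, 31.6% high risk,
5-year median and follow-up) this yields d = 26.6 events and 73 cases.
Weighting by event proportion rather than allocation proportion is the
variant that reproduces the published case count; both quantities are
close here because censoring is moderate.

### Unsupervised clustering

Hierarchical clustering uses 1 - Pearson correlation between patient
profiles with complete linkage; the similarity-profile variant builds
the patient-by-patient Spearman matrix and clusters its rows by
Euclidean distance (complete linkage, default 3 clusters). Constant
rows/profiles are an error naming the offending row, since their
correlation is undefined.

## Robustness

Mask deformations apply |k| iterations of 6-connected binary
erosion/dilation ("k voxels" = k morphological steps; a ball element of
radius k would be an alternative reading, and the cross element is the
conservative one). The four RPV features are recomputed per deformation
with the wavelet decomposition shared across deformations (it is
mask-independent). Erosion to emptiness is flagged and excluded from
summary means/sds with an explicit count. The report also carries the
Spearman correlation of delta-RPV against k as a diagnostic; its sign
depends on the contrast between tumor and surrounding tissue and is
*not* asserted — see limitations.

Feature-wise reproducibility correlates the strict upper triangles of
the two cohorts' feature-feature Pearson matrices; constant features are
excluded pairwise with a warning. The batch check standardizes features,
takes the leading 5 principal components, and tests each against batch
labels with Kruskal-Wallis, BH-adjusted.

## Synthetic data

**Phantom** (defaults): 64^3 grid at 1 mm isotropic spacing; ellipsoidal
tumor (semi-axes 20/22/18 voxels) with an enhancing solid rim
(60 +/- 15 HU) around a cystic core (10 +/- 8 HU, 40% of the tumor
volume, cut at equal-volume-fraction normalized radius), in soft-tissue
parenchyma background (30 HU); a Gaussian random field (correlation
length 2 voxels, sd 20 HU) adds spatial texture. Each artifact draws
from its own stream derived from the user seed, so adding generator
calls never perturbs existing fixtures.

**Cohort** (defaults): n = 400 patients; 42 candidate features in blocks
of 6 with within-block correlation 0.3; four planted log hazard ratios
(+0.8, -0.8, +0.6, -0.6) on features in distinct blocks — mirroring the
42-candidate -> 4-feature reduction shape of the discovery problem;
exponential baseline with 36-month median; administrative censoring
uniform on (0, 72) months (about half the patients are events); 15% of
patients carry two bilateral tumor rows whose features differ by
N(0, 0.2) noise; stage/age/residual-disease/slice-thickness/neoadjuvant
covariates drawn independently of the features.

**What the phantom experiments show and don't.** The phantom exercises
every numerical path (geometry, discretization, filtering, all feature
families) and the cohort generator verifies the statistical machinery
(FDR control, selection consistency, concordance) under a known truth.
They do not emulate scanner physics, reconstruction kernels, contrast
phase, or real tumor morphology; in particular, the direction of RPV
drift under mask erosion/dilation observed on real tumors reflects
tissue contrasts the phantom does not reproduce, so that finding is
reported as a diagnostic, not asserted. Cohort-level stability constants
and cross-cohort reproducibility values from the original study require
the original scans and are out of scope.

## Problem sizes in tests and the acceptance script

Tests run the texture-vs-brute-force comparison on 100 random grids up
to 6^3 with up to 4 gray levels; the recovery experiment uses 100
replicates of the n=400 cohort for the selection rate, and smaller
replicate counts (5-10) for screened power/FDR spot checks.
`scripts/acceptance.py` reports the same quantities with 25 cohort
replicates and 50 oracle grids; these sizes are the package's choices
for routine verification and can be raised via `--replicates`.

## Known limitations

* The 657-name enumeration reproduces the four published family groups
  and the published naming grammar, but the per-family statistic lists
  are this package's reconstruction; counts and ordering are pinned by a
  golden test rather than by an external table.
* DICOM support covers single-frame axial CT series with uniform
  orientation; no de-identification, registration, or contrast-phase
  logic.
* The penalized-Cox path depends on the coordinate-descent solver's
  penalty grid; the CV-optimal penalty is recorded in the signature
  model for reproducibility.
* 2D in-plane (slice-wise) deformation and texture variants are not
  implemented; all operations are fully 3D.
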