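# Methods

This note records the modeling and numerical choices behind `bcsradiomics`:
what each stage computes, the conventions pinned where the field's
literature is ambiguous, what the phantom generator does and does not
emulate, and the limitations a user should keep in mind.

## Problem setting

After breast conservation surgery (BCS), pathology sometimes finds tumor at
or within 1 mm of the inked specimen margin, and the patient returns for
re-excision.  The pipeline models the binary endpoint *re-excision
(label 1) vs clean initial excision (label 0)* from quantitative features
of the contoured tumor on preoperative DCE-MRI: one pre-contrast and three
post-contrast T1-weighted fat-suppressed series.  A single hand-drawn
contour (in practice drawn on the first post-contrast series) is mapped
onto all four timepoints, so the pipeline assumes one mask per lesion and
no inter-timepoint registration.

## Feature definitions and conventions

**Shape** (computed once per lesion, on the shared mask; reported under the
`pre.` prefix):

- *Solidity* = foreground voxel count / number of grid voxels whose centers
  lie inside or on the convex hull of the foreground voxel centers.
  Counting hull *voxels* rather than comparing continuous mesh volumes
  keeps the numerator and denominator in the same discretization, so a
  convex digital body scores exactly 1.  Hull membership is evaluated by
  Delaunay triangulation of the hull vertices; results are clipped to ≤ 1.
  Masks whose foreground is coplanar or collinear have no 3D hull and fail
  loudly (`DegenerateMaskError`); the extraction stage logs and skips such
  lesions rather than imputing.
- *Extent* = foreground voxel count / tight axis-aligned bounding-box
  volume in voxels.
- *Eccentricity* = `sqrt(1 − λ_min/λ_max)` over the eigenvalues of the
  covariance of foreground voxel centers scaled by voxel spacing (mm).
  This is a 3D ellipsoid-fit meridional eccentricity, contrasting the
  longest against the shortest principal axis; the definition is isolated
  behind one function so an alternative axis pairing is a one-line change.
  A single voxel is defined to have eccentricity 0.

Voxel-count ratios carry a discretization convention worth knowing: a
digital ball whose center sits *between* voxels spans 2r voxels per axis
and its extent converges to π/6 ≈ 0.524; centered *on* a voxel it spans
2r + 1 and the ratio is biased low by O(1/r).  The tests use the
half-offset convention when checking continuous closed forms.

**Histogram** (per timepoint, raw intensities, in-mask only): minimum,
median (midpoint convention for even counts), mean, population variance
(divisor n), skewness `m₃/m₂^{3/2}`, kurtosis `m₄/m₂²` (Pearson,
non-excess: a normal distribution scores 3; "flatness" wording in the
clinical literature fits either convention, so the choice is global and
recorded here).  A constant ROI has undefined skewness/kurtosis, reported
as NaN — never silently 0.

**Quantization**: per scan, equal-width bins over the in-mask range,
`level = min(L, floor((v − min)/(max − min)·L) + 1)`, L = 16.  Per-scan
normalization makes texture features invariant to global intensity scaling
of each sequence (MR intensities are not calibrated units).  A constant
ROI legally maps to level 1 everywhere.

**GLCM**: co-occurrences of level pairs over the 13 unique 3D directions at
voxel distance 1 (both configurable), both voxels in-mask, accumulated
symmetrically into one aggregate matrix and normalized.  One summed matrix
rather than per-direction averaging: fewer arbitrary numbers, and lesion
texture has no preferred axis here.  Features: energy Σp², entropy
−Σp·log₂p (0·log 0 = 0), homogeneity Σp/(1+|i−j|) (inverse difference, not
inverse difference moment), contrast Σp(i−j)².

**GLSZM**: zones are maximal 26-connected components of equal level
(6-connectivity available); `counts[i, j]` = zones of level i, size j.
The 11 statistics follow the standard zone-emphasis family (SZE, LZE,
LIZE, HIZE, LISZE, HISZE, LILZE, HILZE, GLN, ZSN, ZP = N_zones/N_voxels).
Both matrix builders are validated against independent brute-force oracles
(pair enumeration; BFS flood fill) for exact equality, and the voxel
conservation law Σ counts·j = N_voxels is asserted on every synthetic
lesion.

## Univariate screening

Spearman Rs (average ranks for ties; p from the t approximation with n − 2
df, exact permutation enumeration available for n ≤ 10) with the sign
convention *positive Rs = larger feature values in the re-excision group*,
and a two-sample t-test (pooled variance by default, Welch by flag),
reported side by side without reconciliation.  No multiple-testing
correction enters any selection step, matching the single-threshold
(p < 0.05) practice of the clinical analysis this mirrors; a
Benjamini–Hochberg column (`p_spearman_bh`) is emitted as a clearly
labeled extension.  Clinical cohort tables use Pearson chi-square without
continuity correction, falling back to Fisher's exact test for 2×2 tables
with any expected count below 5; borderline receptor categories are kept
as their own column.

## Classifier

RBF-SVM with C = 1000 and γ = 0.005, fixed rather than tuned.  Features
are z-scored per feature with training-fold statistics — with γ this small
the kernel is scale-sensitive, so standardization is material, explicit
and test-covered.  Leave-one-out cross-validation: for each held-out
lesion, the remaining n − 1 rows are standardized and ranked by BW-ratio
from scratch (the held-out row never influences selection or scaling — the
tests re-derive every fold's ranking independently to prove it), and SVMs
are trained on the top k features for all k ≤ 30 within the same fold.
Zero within-class scatter with nonzero between-class scatter gives
BW = +∞ (a perfect separator, ranked first); ties break by feature name
for determinism.  Reported per k: accuracy, sensitivity (fraction of
re-excision lesions correctly classified), specificity (fraction of
no-re-excision lesions correctly classified), each with exact
Clopper–Pearson 95% CIs.  `best_k` is the smallest k maximizing accuracy;
the consensus feature list aggregates per-fold rankings by mean rank at
that k.  No class weighting; the label-permutation null (mean LOOCV
accuracy 0.5 ± 0.1 over 20 permutations) guards against optimism from the
fold-local selection machinery.

## Phantom cohort generator

The generator replaces unavailable patient MRIs with ground-truthed
volumes whose two classes differ in the directions reported clinically.

**Geometry.**  A superellipsoid `Σ|x_i/r_i|^p ≤ 1` (corner exponent
p = 3.2; p = 2 recovers a true ellipsoid) perturbed by K = 8 surface
Gaussian bumps: along direction u the surface sits at radius
`1 + Σ_k a_k exp(−angle(u,u_k)²/2s_k²)` in units of the base radius, with
widths s_k ~ U(0.2, 0.4) rad and amplitudes a_k = irregularity · U(0.4, 1.2).
Amplitudes are *outward* lobes by design: at desk-scale lesion radii
(~10 voxels) an inward radial dent is either voxelized away or merely
shrinks the body while leaving it convex, so denting barely moves
solidity; lobulation — and the clefts between lobes that the convex hull
bridges — is what actually produces the low-solidity, low-extent
morphology of irregular tumors.  Measured control: irregularity
0 / 0.4 / 0.8 → mean solidity 1.00 / 0.99 / 0.86, monotone.  The largest
26-connected component is kept and holes filled (one solid lesion per
volume); lesions touching the grid boundary raise an error.

**Intensity.**  Per lesion one spatially correlated skew-normal field is
built by the additive representation `δ|Z₀| + sqrt(1 − δ²)Z₁`,
δ = a/√(1+a²), from two independent Gaussian-smoothed
(σ = `texture_corr_length` voxels) standard-normal fields.  Smoothing an
i.i.d. skew-normal field directly would *not* work: averaging symmetrizes
the marginal (central-limit effect), leaving sample skewness ~0.1 and
sign-unstable at shape 10, whereas the additive construction keeps the
marginal exactly skew-normal at any correlation length.  The marginal is
then standardized to mean 0, variance 1, so `skew_shape` moves only the
histogram *shape* (skewness, kurtosis, minimum), not its location or
scale.  Timepoint t is `gain · enhancement_curve[t] · uptake · field`
in-mask (uptake jitter applied to post-contrast series only) and low-level
Gaussian background noise outside.  The per-lesion gain and uptake factors
(U(0.9, 1.1)) exist because without them the class-specific enhancement
curves would make mean intensity a deterministic, perfectly separating
feature — a degeneracy no clinical cohort exhibits.

**Calibrated presets** (the default study conditions):

| parameter | class 0 (no re-excision) | class 1 (re-excision) |
|---|---|---|
| irregularity | 0.3 | 0.55 |
| skew_shape | 0 | 3.0 |
| enhancement curve | (1, 2.1, 1.9, 1.7) | (1, 2.3, 2.1, 1.9) |
| texture corr. length | 1.2 vox | 1.5 vox |
| base radii | (9, 8, 7) vox | (10, 8, 6) vox |

yielding class-mean solidity ≈ 0.98 vs 0.92 and extent ≈ 0.55 vs 0.44
(both inside the plausible clinical bands 0.70–0.99 and 0.40–0.80), and
post-contrast skewness ≈ 0 vs ≈ 0.6.  Per-lesion size varies by ±15%
isotropic scaling.  Grid 52³ voxels at (1, 1, 3) mm spacing, echoing
thick-slice sagittal breast protocols.  Determinism: every lesion's
streams derive from `SeedSequence([master_seed, label, index])`, so
cohorts are reproducible and extensible without reshuffling existing
lesions.

**What the phantoms do not emulate** — and hence what passing tests do and
do not show.  No bias field, motion, fat-suppression failure, partial
voluming, multifocal disease, or contour variability; class differences
are cleaner and larger than clinical effect sizes (synthetic univariate
|Rs| ≈ 0.8 where clinical values run ~0.3).  Tests on phantoms therefore
validate the *correctness of the machinery* — feature definitions against
closed forms and oracles, leakage-free fold-local selection, direction
recovery — not clinical discriminative performance; the near-perfect
phantom operating points are an upper bound with no clinical meaning.

## Problem sizes and numerics

Default validation runs use 50 lesions per class on the 52³ grid for
recovery checks, 10 per class for invariant suites, and 100 random arrays
up to 6×6×5 for oracle equivalence — sizes chosen so the whole suite runs
comfortably on a laptop-class single core.  Degenerate inputs are defined
behavior throughout: constant ROI → level 1 everywhere (quantization) and
NaN-with-flag (moments); single voxel → eccentricity 0, extent 1; masks
without valid neighbor pairs → explicit GLCM error; constant features →
flagged, excluded from screening output rather than propagated as NaN.

## Known limitations

- Eccentricity's 3D covariance definition is one of several in circulation
  (2D slice-wise ellipse fits exist in older clinical software); results
  are not comparable across conventions.
- The GLCM/GLSZM conventions (aggregation, homogeneity form, connectivity,
  per-ROI quantization range) are documented choices, not a compliance
  certification against any standardization initiative.
- Exact Spearman permutation p-values are opt-in and practical only for
  n ≤ 10 (factorial enumeration).
- The clinical reference tables bundled in `bcsradiomics.clinical` are
  group-level counts; continuous patient-level variables cannot be
  reconstructed from them, so t-tests on those variables are available
  only for user-supplied records.
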