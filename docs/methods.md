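# Methods

This document records what `gliorad` computes, the conventions it follows, and
the reasoning behind its parameter defaults and numerical choices. It is the
companion to the API documentation: the API says *how to call* things, this
says *what they mean*.

## 1. Problem and model

The package implements a radiomic pipeline for binary tumor-grade
classification of malignant gliomas (WHO grade III vs grade IV) from paired
contrast-enhanced T1-weighted (CE-T1) and T2-weighted MRI volumes with a
segmented tumor region of interest (ROI). Grade IV is the positive class
throughout.

The statistical model is a two-stage sparse classifier over a fixed,
enumerable feature space:

1. **Feature extraction** maps each subject to a 5912-dimensional vector of
   shape, intensity, histogram, and texture descriptors computed on the
   original images and on eight wavelet sub-bands (Section 5).
2. **Feature selection** combines a univariate Wilcoxon–Mann–Whitney (WMW)
   screen at p < 0.001 with an L1-penalized (LASSO) logistic regression whose
   penalty is tuned by repeated stratified cross-validation (Section 6).
3. **Classification** fits five standard classifiers on the selected columns
   and evaluates them with leave-one-out cross-validation (LOOCV) in which the
   *entire* selection protocol is repeated inside every fold, plus an
   independent-validation step restricted to the features selected in all
   folds (Section 7).

Real patient data never ships with the package. A synthetic phantom cohort
generator (Section 2) provides controllable stand-in data for testing and
demonstration; it is first-class, tested code, not a fixture dump.

## 2. Phantom cohort design

`generate_cohort` produces subjects consisting of a CE-T1 volume, a T2
volume, a brain mask, and a contiguous tumor mask on a common grid.
Images are generated directly on an intensity scale with zero mean and unit
variance over the brain (a "Z scale"), so planted class effects are expressed
in interpretable SD units.

Per-class differences are controlled by `ClassEffects`:

| knob | default | meaning |
|---|---|---|
| `intensity_shift` | 1.5 | additive CE-T1 ROI shift (in brain-SD units) for grade IV |
| `texture_smoothness_ratio` | 2.0 | ratio of intra-tumor texture correlation lengths (grade IV smoother) |
| `tumor_radius_ratio` | 1.4 | grade IV / grade III mean tumor radius ratio |

Setting all three to their neutral values (0, 1, 1) yields a **null cohort**
in which grade labels are independent of the images; this is the package's
negative control for the evaluation machinery.

Other defaults: `noise_sigma = 0.3` (voxel-wise Gaussian noise, brain-SD
units), tumor radius ≈ 14 % of the grid edge, minimum grid 16³. Each subject
draws from `numpy` `SeedSequence([seed, cohort_key, subject_index])`, so
subjects are independent, cohorts with different tags are independent, and
everything is reproducible from one integer seed. Degenerate draws (e.g. a
tumor that leaves the brain) are retried up to 10 times, then raise
`DegeneratePhantom` rather than silently returning malformed data.

What the phantom does **not** emulate: bias fields, partial-volume effects,
registration error between sequences, anisotropic acquisition artifacts, or
realistic tumor morphology (tumors are smoothly deformed blobs). It exists to
give the pipeline signals whose ground truth is known, not to imitate
clinical images.

## 3. Preprocessing

- **Z-score normalization** (`zscore_normalize`): each volume is shifted and
  scaled by the mean and *population* standard deviation computed over the
  whole-brain mask, and the transform is applied to every voxel (inside and
  outside the brain). A brain SD below 10⁻¹² of the mean magnitude raises
  `DegenerateIntensity`.
- **Isotropic resampling** (`resample_image_isotropic`): cubic B-spline
  interpolation (`scipy.ndimage.map_coordinates`, order 3, nearest-edge
  mode) onto a 1 mm isotropic grid; the new shape is `round(n·s / target)`
  per axis.
- **Mask resampling** (`resample_mask_isotropic`): shape-based interpolation.
  The binary mask is converted to a signed Euclidean distance map (positive
  inside, via `distance_transform_edt`), the distance map is resampled with
  the same cubic spline, and the result is thresholded at ≥ 0. This keeps
  interpolated boundaries smooth and avoids the stair-stepping of
  nearest-neighbour mask resampling. Already-isotropic inputs short-circuit
  to an identity copy.

Normalization uses whole-brain statistics (not ROI statistics) so that the
ROI mean itself remains an informative feature.

## 4. Wavelet decomposition

`WaveletBank` computes a single-level **undecimated** (stationary) 3D wavelet
decomposition with the Coiflet-1 filter pair, yielding eight equally-sized
sub-bands `HHH … LLL` — every combination of high-/low-pass along the three
axes. Filtering is separable correlation (`scipy.ndimage.correlate1d` with
the reversed filter, i.e. true convolution) with `reflect` boundary handling
and the conventional centering offset `c = L − 1 − L//2` for a length-`L`
filter. Because no decimation is applied, each sub-band is voxel-aligned
with the input and the original ROI mask applies unchanged. Inputs smaller
than the filter support raise `ImageTooSmall`.

Correctness is pinned in tests against a direct (triple-loop) 3D convolution
oracle on impulse and random inputs.

## 5. Features

### Quantization

Texture features are computed on gray levels quantized by **fixed bin count**
over the robust range **μ ± 3σ** of the ROI intensities (population σ):

```
level(v) = min(N_g, 1 + floor(N_g · (v − lo) / (hi − lo))),  v clipped to [lo, hi]
```

with `N_g = 2^bits` for bits ∈ {4, 5, 6, 7, 8}. If σ is numerically zero
(relative threshold 10⁻¹³) the ROI is degenerate: all voxels map to level 1
and a warning is issued.

### Texture families and conventions

| family | size | convention |
|---|---|---|
| GLCM | 11 | 13 unique 3D directions, distance 1, symmetrized, **merged** into one normalized matrix |
| GLRLM | 13 | runs along the same 13 directions, merged |
| GLSZM | 13 | zones are 26-connected components of equal level (`skimage.measure.label`, connectivity 3) |
| NGLDM | 16 | coarseness parameter α = 0; dependence count k stored at column index k + 1 |
| NGTDM | 5 | per-level sums sᵢ of |level − neighbourhood mean| with counts nᵢ; coarseness guarded by ε = 10⁻¹² |

All five matrix builders are verified cell-for-cell against independent
brute-force (triple-loop) oracles on batches of random ROIs. Scalar features
on an all-zero matrix (single-voxel ROI) return 0 with a warning rather than
NaN.

### First-order and shape

- **Intensity** (18): moments (population variance/skewness/excess kurtosis),
  order statistics, energy/RMS, MAD, robust variants.
- **Histogram** (20): the intensity set recomputed on a fixed 6-bit (64-level)
  quantization, plus entropy, uniformity, mode, and maximum histogram
  gradient.
- **Shape** (8): volume, surface area, surface-to-volume ratio, sphericity,
  compactness, spherical disproportion, maximum 3D diameter (convex-hull
  vertices), and elongation-type descriptors.

**Surface convention.** Two surface definitions are deliberately in play.
`surface_area` and `surface_to_volume_ratio` count exposed voxel faces —
exact for axis-aligned shapes (a 10 mm cube has exactly 600 mm²). The
*shape-regularity* features (sphericity, compactness, spherical
disproportion) instead use a marching-cubes mesh surface: face counting
over-estimates the area of smooth shapes by up to 50 % (a digital ball's
face-count sphericity tends to 2/3 regardless of radius), which would make
"how sphere-like" features structurally unable to approach 1. With the mesh
surface a radius-15-voxel ball scores sphericity ≈ 0.98. Note that even
mesh-based sphericity is not strictly monotone in radius at voxel
resolution; area fluctuations of ~0.5 % between nearby radii are normal.

### Feature-space enumeration

The full space is generated deterministically by `enumerate_feature_space`:

```
8 shape                                      (mask, once)
+ 2 sequences × 9 versions × (18 + 20)       intensity + histogram
+ 2 sequences × 9 versions × 5 bit-depths × (11+13+13+16+5)  texture
= 8 + 2·9·38 + 2·9·5·58 = 8 + 684 + 5220 = 5912
```

where the 9 versions are the original image plus 8 wavelet sub-bands. Every
feature has a canonical string name `sequence|filter|quantization|family|name`
(e.g. `CE-T1|HLL|7bit|GLSZM|gray_level_variance`) that round-trips through
`FeatureDescriptor.parse`.

## 6. Feature selection

### Stage 1 — WMW screen

Each column is tested with the two-sided Wilcoxon–Mann–Whitney test; columns
with p < 0.001 survive. Implementation: `scipy.stats.mannwhitneyu`,
vectorized asymptotic path with tie and continuity corrections; the exact
(enumeration) path is used when both groups have ≤ 8 subjects and the column
is tie-free. Constant columns get p = 1. The exact path is cross-checked in
tests against an independent `itertools` rank-enumeration oracle.

A caution on the normal approximation: at n = 8 + 8 its worst-case absolute
error versus exact enumeration is ≈ 0.011 (at mid-range p ≈ 0.38); in the
decision-relevant tail (p < 0.01) it is ~10⁻³. The implementation sidesteps
the issue at such small group sizes by using the exact path.

### Stage 2 — LASSO-logistic

The selector minimizes summed logistic loss plus λ‖β‖₁ with an unpenalized
intercept, implemented as cyclic proximal coordinate descent with the
standard ¼-curvature majorization (inner loop JIT-compiled with `numba`).
Correctness is pinned against KKT conditions at λ_max =
max_j |Σᵢ x_ij (yᵢ − ȳ)|, against `scikit-learn`'s L1 logistic solver at
tight tolerance, and against brute-force objective grids. (`scikit-learn` is
used only as a test oracle here; the production path is the package's own
solver.)

λ is tuned over `logspace(−6, 2, 33)` by 5-repeat, 5-fold stratified CV,
maximizing mean validation AUC; ties resolve to the **largest** (sparsest) λ.
The path is warm-started from large to small λ. Selected features are the
non-zero coordinates of the final fit at λ*.

`SelectionEmpty` is raised only when the *screen* passes zero columns. A
LASSO fit whose slopes are all zero is a legitimate outcome and yields an
intercept-only model.

## 7. Models and evaluation

Five classifiers are evaluated (`scikit-learn` estimators behind the
package's own tuning and CV plumbing): logistic regression (LR), RBF-kernel
SVM with Platt-calibrated probabilities (SVM), a small single-hidden-layer
neural network (SNN), a 1000-tree random forest (RF), and Gaussian naive
Bayes (NB). Inputs to every model are standardized with training-fold
statistics only.

- **LOOCV with per-fold reselection**: for each held-out subject, screening,
  λ tuning, the final LASSO fit, and per-model hyper-parameter tuning are all
  re-run on the remaining subjects. Pooled out-of-fold probabilities give
  accuracy/sensitivity/specificity at threshold 0.5 and the AUC (own
  rank-based implementation with proper tie handling, verified against an
  exhaustive pair-counting oracle).
- **Failed folds**: a fold whose screen is empty is recorded as failed and
  its held-out subject scores **0.5** — an explicit ROC tie. Likewise the
  intercept-only fallback scores 0.5, *not* the training base rate: in LOOCV
  the base rate anti-correlates with the held-out label (removing a positive
  subject lowers it), which would push null-data AUC spuriously below 0.5.
  The failed-fold count is reported alongside the metrics.
- **Independent validation**: the features selected in *every* LOOCV fold
  (the intersection) are refit on the full primary cohort and evaluated once
  on an untouched validation cohort. An empty intersection raises
  `EmptyIntersection`.
- **Across-model summary**: mean, *sample* SD (ddof = 1), and a t-based 95 %
  CI across the five models, flagged `low_n` below five models. With five
  values the t interval is mean ± 2.776·s/√5.

### Pooled-LOOCV bias

Pooling out-of-fold scores from per-fold-selected models is the protocol
implemented, and it is known to be a biased estimator of AUC: on pure-noise
data with p ≫ n it can stray well above or below 0.5 (we have reproduced
pooled AUCs ≈ 0.74 on iid noise with an independent minimal
scipy/scikit-learn script — it is a property of the protocol, not a bug),
and on strongly correlated features it can be pessimistic. This is why the
package's own null-cohort checks assert a *band* around chance rather than
exact 0.5, and why independent validation on a held-out cohort is part of
the default study layout.

## 8. Numerical choices

| choice | value | why |
|---|---|---|
| CD convergence (final fit) | tol 10⁻⁷, ≤ 10⁴ sweeps | selection decisions need tight coefficients |
| CD convergence (inside CV) | tol 10⁻⁴, ≤ 500 sweeps | CV only ranks λ values; looser tolerance changes nothing detectable and cuts LOOCV time ~10× |
| separation guard `eta_cap = 35` | stop when min |xβ| > 35 | on separable folds at tiny λ the unregularized logit diverges; beyond |η| = 35 every probability is within 10⁻¹⁵ of 0/1 and further sweeps are pure cost |
| quantizer degeneracy | σ ≤ 10⁻¹³·max(1, |μ|) | relative test; absolute round-off on constant ROIs is ~10⁻¹⁶ |
| NGTDM coarseness | ε = 10⁻¹² in 1/(Σ pᵢsᵢ + ε) | keeps the feature finite on uniform ROIs |
| λ grid | logspace(−6, 2, 33) | 4 points/decade over 8 decades |
| "desk" scale | 48³ grids, ~30+30 subjects, filters {orig, LLL, HHH}, bits {4, 8} (932 features), fixed desk hyper-parameters, RF 100 trees | package-chosen problem sizes that keep the full end-to-end test suite within a routine CI budget while still exercising every stage, including per-fold reselection |

The desk scale reduces breadth (fewer filters/bit-depths, no per-model grid
search inside LOOCV), never the protocol: screening, λ tuning, and the final
LASSO fit are still re-run inside every fold.

## 9. Known limitations

- The phantom is a stylized generative model (Section 2); effect sizes
  recoverable on it do not translate directly to clinical effect sizes.
- Pooled-LOOCV AUC is biased in both directions depending on the data regime
  (Section 7); treat it as a protocol-faithful score, not an unbiased
  generalization estimate.
- Texture features are single-scale (distance-1 neighbourhoods, one wavelet
  level).
- The WMW screen tests columns marginally; jointly informative but
  marginally silent feature pairs are invisible to stage 1 by design.
- Surface-derived shape features are voxel-resolution dependent (Section 5);
  compare them only across images resampled to the same spacing, which the
  default pipeline enforces.
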