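# Methods

This note records the models, conventions and numerical choices behind
`plaqseg`, and what the synthetic phantom does and does not establish
about real data.

## Problem setting and assumptions

The package classifies every voxel of a segmented carotid vessel wall
into calcification (C), fibrous tissue (F) or lipid-rich necrotic core
(LRNC) from six co-registered channels (five MR contrasts and CTA).
Training labels are assumed to come from reference segmentations — in
practice histology registered to the in vivo scans — that are correct
as *tissue maps* but spatially misplaced by a residual registration
error of the order of a millimetre.  The label-uncertainty machinery
exists to keep that spatial error from biasing the classifier.  The
inputs are assumed bias-field-corrected and co-registered; no
inter-modality registration is performed here.

All volumes are `(slice, row, col)` arrays with spacing
`(dz, dy, dx)` in mm; physical position is `index × spacing`.  The
class order (C, F, LRNC) is fixed and every tie — posterior ties,
one-vs-one vote ties, label-resampling ties — resolves to the lowest
class index.

## Preprocessing

MR channels are normalized to mean 0 / SD 100 inside the region of
interest (the in vivo outer-wall mask in the pipeline); the CTA channel
keeps its original intensities, since its absolute (Hounsfield-like)
scale is itself informative for calcium.  All channels and label maps
are resampled to 0.25×0.25 mm in-plane (through-plane spacing is left
unchanged): intensities by cubic B-spline interpolation, label maps by
linear interpolation of per-class indicators followed by argmax, which
guarantees the result is still a partition.  Distance maps are signed
Euclidean distances (negative inside the mask) computed by exact
distance transform with physical sampling; features use the unsigned
values.  Registration quality is summarized by the per-slice wall Dice
overlap and by the symmetric mean in-plane contour distance.

Whether the per-slice Dice should be computed on the original or the
resampled grid is not determined by the protocol; the pipeline computes
it on the resampled working grid, where the soft labels that consume it
live.

## Features

24 features per voxel: 5 normalized MR intensities, the same 5 blurred
at σ = 1 mm, 5 gradient magnitudes and 5 Laplacians at that scale
(derivatives per mm, honouring anisotropic spacing), the CTA intensity,
d_lum, d_out, and d_lum·d_out.  Derivatives are computed in-plane (2D
per slice): the 1.5 mm slice thickness exceeds the kernel scale and the
whole analysis is slice-oriented, so 3D kernels would mostly mix
independent slices.  The second-derivative kernel is the sampled
Gaussian second derivative with an exact zero-sum correction so
constant images have identically zero Laplacian.  Training-row
distances come from the reference geometry and testing-row distances
from the in vivo geometry, mirroring what is knowable at train and test
time.

Training uses a fixed 10% subsample of the voxels inside both walls,
drawn by a seeded permutation stratified by subject and slice with
floor rounding; the subsample depends only on the pipeline seed and the
subject, so every method configuration reuses identical training
voxels.

## Label-uncertainty strategies

**Soft labels.**  w^c(x) = Dice_s^n · (G_σ∗M_c)(x) / Σ_c′(G_σ∗M_c′)(x).
The blur is 2D in-plane, consistent with the slice-wise Dice.  σ = 0
and n = 0 reproduce the one-hot hard labels bit-exactly, which makes
the hard-label pipeline a special case rather than a separate code
path.  Voxels outside all blurred supports, and slices whose Dice is
undefined (both walls empty), are excluded from training.

**Contour-distance weights.**  The local contour difference δ is the
absolute difference of the two geometries' unsigned distance maps — a
smooth, everywhere-defined surrogate for the nearest-contour offset
with the required endpoints (weight 1 at δ = 0, 0 at δ = 5 mm, linear
between).  The lumen and outer weights are mixed as
w = (1−r)·w_lum + r·w_out with r = d_lum/(d_lum+d_out) from the in
vivo distances, so lumen agreement governs near the lumen and
outer-wall agreement near the outer boundary.  Voxels with
d_lum + d_out = 0 are excluded with a warning.

**Gaussian outlier rejection.**  Per class, mean and covariance are
estimated by iterating: Mahalanobis distances under the current
estimate, weights exp(−d²/2) floored at 1e-12, weighted mean and
covariance.  The weighted covariance carries a Gaussian consistency
factor of 2: for clean Gaussian data the uncorrected weighted
covariance estimates Σ/2 per sweep (its fixed point is 0), whereas with
the factor Σ is the unique, contractive fixed point — so the clean-data
fit agrees with the plain sample estimates.  The covariance is
ridge-regularized by 1e-6·trace/d·I; iteration stops at relative
parameter change < 1e-8 or 50 sweeps.  The ceil(fraction·n) samples
with the largest Mahalanobis distance are rejected (default fraction
0.10), ties broken by stable row order so the count is exact and the
result permutation-invariant.  The fit needs at least d+2 samples per
class; with 24 features this sets a real lower bound on per-class
training-set size, which the phantom defaults respect.

## Classifiers

The weighted LDC estimates μ_k as the w_k-weighted mean, the pooled
covariance as the weighted within-class scatter divided by
(total weight − K), and priors as normalized class-weight totals.  The
denominator choice makes integer weights exactly equivalent to sample
replication and one-hot weights exactly equivalent to classical LDA.  A
singular pooled covariance is ridge-repaired (1e-8·trace/d, with an
absolute floor when the scatter is identically zero) and logged.
Posteriors are computed in log space via Cholesky factorization.

The SVM side trains one libsvm binary machine per class pair on
features standardized to zero mean / unit SD using the statistics of
the positive-weight training samples only — this makes zero weight
exactly equivalent to sample removal.  Sample i enters with effective
penalty C·w_i.  For soft labels the pairwise machine uses the weight of
the sample's hard class (how soft per-class weights should enter a
pairwise hinge loss is not otherwise determined); multiclass labels
come from one-vs-one majority voting.

## Evaluation protocol

Leave-one-subject-out: train on all other subjects' 10% subsamples
with the configured weights, classify every in vivo wall voxel of the
held-out subject.  Free hyperparameters (σ, n for soft labels; C, γ for
the SVM) are chosen by a nested leave-one-subject-out grid search over
σ ∈ {0, 0.25, 0.5, 0.75, 1, 1.5, 2} mm, n ∈ {0, 3, …, 39},
C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1, 1}, minimizing the per-slice
absolute volume error of the three components averaged with equal
slice weight — measured against the *reference* labels, since the
phantom's hidden truth has no counterpart in real data and must not
leak into selection.  Grid ties resolve to the lexicographically
smallest parameters.  The C/γ grid is a small conventional default
(the protocol itself does not fix one) and is overridable in the
configuration.

Reported metrics: per-subject and per-slice relative volumes
(% of wall voxels), bias (pred − truth), absolute error, and Spearman ρ
with midranks.  Methods are compared by the Friedman test on per-slice
component-averaged absolute errors (scipy for ≥3 methods, the classical
midrank chi-square inline for 2), reported as the statistic, p-value
and mean-rank table plus Bonferroni-corrected pairwise sign tests —
used here in place of a Tukey–Kramer post-hoc, whose recipe on Friedman
ranks is under-determined.  A greedy forward-selection diagnostic
(LDC training accuracy, pairwise classes, ties by column order) is
provided for feature-relevance inspection.

## The phantom: what it emulates and what it does not

Each synthetic subject is a slice-wise annular vessel (lumen inside an
outer wall, with slow axial drift and radius modulation) whose wall is
partitioned into a compact calcification blob near the outer boundary,
a larger necrotic-core blob near the lumen, and fibrous tissue
elsewhere, with exact target counts (defaults 5/60/35% of wall
voxels).  Intensities are per-class constants plus white Gaussian
noise.  The default contrasts encode the modality asymmetry of real
plaque imaging: calcification is the uniquely bright class in CTA but
nearly isointense with fibrous tissue in MR (combined five-channel
separation ≈ 0.7 Mahalanobis units), while the fibrous/LRNC contrast
exists only in MR (strongest post-contrast; combined separation ≈ 2
units, i.e. per-voxel two-class Bayes accuracy ≈ 80%) — a substantial-
overlap regime rather than a toy-separable one.

Misregistration is simulated by warping the reference labels and
geometry with a per-slice sum of four Gaussian-bump displacement
kernels with random centres and orientations, rescaled so the peak
magnitude equals the requested amplitude.  Kernel widths (16–32 mm) are
large relative to the vessel, giving slice-wide low-frequency
distortions: at the default 1.5 mm peak the residual mean lumen contour
offset is ≈ 0.7 mm and the wall Dice ≈ 0.8, the order of the residual
error real histology-registration pipelines leave behind.  Labels and
masks are warped together as one code map by nearest-neighbour
pullback, so mutual exclusivity and the wall partition survive warping
exactly.  Amplitude 0 is a strict identity.

The phantom has no texture, no bias fields, no CT blooming, no
histology-processing artifacts (shrinkage, tearing), and its class
intensities are constants — so passing tests demonstrate the
correctness and the qualitative behaviour of the machinery (e.g. that
outlier rejection recovers accuracy lost to misregistered labels), not
clinical-grade performance on patient data.  Absolute phantom volume
errors are far smaller than errors on real plaque.

## Problem sizes

Default phantom subjects are 6 slices of 96×96 voxels at 0.5 mm
in-plane (resampled to 0.25 mm by the pipeline), about 3,000 wall
voxels per subject — large enough that each class's 10% training
subsample comfortably exceeds the 24 feature dimensions, small enough
that a six-subject leave-one-out comparison runs in seconds.  These
sizes are the package's chosen desk-scale study conditions; all
protocol constants (0.25 mm grid, 10% subsample, 10% rejection, the
σ/n grid) are independent of them.

## Known limitations

- The robust Gaussian fit requires ≥ d+2 samples per class and degrades
  gracefully but noticeably when the class barely clears that bound.
- Contour-distance weights use distance-map differences, which
  underestimate the true nearest-contour offset where the two contours
  are locally parallel but far apart in the tangential direction.
- The SVM soft-label interpretation (hard-class weight per pair) is one
  of several defensible choices.
- Hyperparameter search retrains the classifier at every grid point;
  with the full σ×n×C×γ product and the SVM this is exhaustive and
  slow — intended usage fixes either the label or the kernel grid.
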