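# Methods

## Overview

`dynrad` measures how stable the *temporal trajectory* of a radiomic
feature over the cardiac cycle is under additive image noise. The unit of
analysis is the (subject, feature) pair; the statistic is the mean
pairwise MAE (mpMAE) of normalized feature curves over all unordered
pairs of noise instances, plus its restriction to same-level pairs. The
pipeline is: simulate → extract → curves → stability/consensus →
classify, each stage a pure function of its inputs and explicit seeds.

## The synthetic phantom

### What it emulates

A single mid-ventricular short-axis cine slice: a circular blood pool
(bright), an annular left-ventricular myocardium (intermediate) and
background (dark), over a closed cardiac cycle of T frames. The
endocardial radius follows a raised cosine,

    r_endo(t) = r_endo_ED − c · r_endo_ED · (1 − cos 2πt/T) / 2,

maximal at t = 0 (end-diastole) and minimal at t = T/2 (end-systole),
with contraction fraction c ∈ [0, 1). The myocardium is treated as
incompressible: the annulus pixel area is held exactly constant across
frames by selecting, at each frame, the target number of nearest pixels
outside r_endo(t) in a fixed stable distance order. The epicardial
boundary is thereby *defined* by area conservation and absorbs all
pixelization error, so the wall thickens as the cavity shrinks.

A smooth texture field — three sinusoidal components with integer spatial
frequencies 1–4 cycles per field of view, phases drawn once from
`texture_seed` — is added to the whole image identically in every frame.
The reference feature curves therefore vary over the cycle purely because
the deforming annulus samples different parts of a fixed texture, which is
the mechanism that makes σ_ref > 0 for most features while keeping
reference curves smooth.

Default parameters (all in pixels / arbitrary intensity units):
grid 128², T = 25 (12–50 allowed), r_endo_ED = 20, r_epi_ED = 30,
contraction fraction 0.3, class means background/myocardium/blood =
50/200/400, texture amplitude 20 (10% of the myocardial mean),
pixel spacing 1.5 mm. These are round numbers in the range of a cropped,
mid-field cine acquisition; none of the analysis depends on their exact
values, only on the ordering blood > myocardium > background and on a
non-degenerate texture.

The cohort generator draws per-subject geometry uniformly from ranges
caricaturing the five standard cine-CMR diagnostic classes (normal;
infarct: mildly dilated, hypokinetic; hypertrophic: thick wall, small
cavity; dilated: large cavity, thin wall, poor function; abnormal right
ventricle: near-normal left ventricle), with frame counts uniform in
12–50 to emulate heterogeneous temporal resolution.

### What it does not emulate

No MRI physics: no coil sensitivity, k-space sampling, partial volume,
papillary muscles, through-plane motion, or Rician magnitude noise (real
magnitude images are Rician, markedly so at low SNR). Noise is iid
zero-mean Gaussian per pixel. Consequently, passing tests show that the
*pipeline* measures stability correctly, not that any specific feature's
stability value transfers to scanner data.

### Noise convention

Sequences are affinely rescaled to [0, 1] by the subject's global
min–max before noise is added, and noise standard deviations are
fractions of that range. This makes the conventional levels
0.010–0.040 meaningful regardless of the raw intensity scale, which is
scanner-dependent in practice. Whether noise should be added to raw or
normalized intensities is a genuine convention choice; the
fraction-of-range form is used throughout and documented here.

Per-instance seeds are the first four bytes of
SHA-256(base_seed | subject | level index | replicate index), reduced
mod 2³¹ — replicates are independent yet exactly reproducible, and
independent of Python hash randomization. A noise std of exactly 0
returns a bitwise-identical copy (no RNG draw), which underpins the
zero-noise identity: with all levels at std 0, every mpMAE is exactly 0.

## Feature engine

All conventions are pinned so that results are bit-reproducible:

- **Discretization**: fixed bin *count* B (default 32) over the
  per-frame, per-filter ROI min–max;
  `level(v) = min(B, floor((v−m)·B/(M−m)) + 1)`; a constant ROI maps to
  level 1. Min–max binning makes all discretized-texture features
  invariant to adding a constant to the ROI.
- **Wavelet**: single-level undecimated 2D Haar transform, orthonormal
  kernels [1,1]/√2 and [1,−1]/√2, periodic boundary; sub-band names give
  the row-axis filter first. The 2D sub-bands LL/LH/HL/HH play the role
  that LLL/…/HHH play in 3D extractions of volumetric data; single-slice
  cine data is intrinsically 2D.
- **LBP**: P = 8 circularly interpolated neighbours at radius 1,
  bilinear interpolation with periodic wrap; rotation-invariant uniform
  codes 0..P (number of neighbours ≥ centre) with P+1 for non-uniform
  patterns. Offsets within 1e-9 of an integer are snapped to the exact
  grid position so that quantized images do not produce interpolation
  ties at the ≥ comparison.
- **GLCM**: offsets (0,1), (1,0), (1,1), (1,−1); in-mask ordered pairs,
  symmetrized by adding the transpose, normalized per offset; features
  averaged over offsets (offsets with no valid pair are dropped). The
  `Correlation` of a single-level ROI is reported as 1 by convention so
  feature curves stay finite; `Idn` normalizes |i−j| by B.
- **GLSZM**: zones are 8-connected components of equal-level in-mask
  pixels (4-connectivity available). Labelling is done on the mask
  bounding box for speed; results are identical.
- **First order**: variance with denominator N; Fisher (excess)
  kurtosis; skewness/kurtosis of a constant ROI defined as 0, and the
  centered residuals of a constant ROI forced to exact zeros so that
  `Variance == 0.0` holds exactly (this feeds the σ_ref = 0 exclusion
  rule); percentiles interpolate linearly between order statistics;
  entropy in bits over the discretized histogram.

Default feature set: 6 filter images × (13 first-order + 9 GLCM +
6 GLSZM) = 168 identifiers, e.g. `wavelet-LH_glcm_Idn`. The engine is
validated against brute-force oracles (exhaustive pair enumeration,
explicit flood fill, per-pixel neighbour enumeration, direct periodic
convolution, literal formula sums) on ≥100 random masked images up to
8×8 with up to 4 levels, to 1e-10, and against scikit-image's
`graycomatrix` on full masks.

## Curves, normalization, stability

Curves are assembled per (subject, feature, instance) from the complete
long-format table (any missing cell is a hard error naming the hole).
Normalization uses the reference curve's mean and *population* standard
deviation (denominator T — the reference curve is the entire population
of its frames); one affine map per (subject, feature) applied to every
instance, never per-instance re-centering. σ_ref = 0 excludes the
feature for that subject; exclusion is per subject, and the consensus is
restricted to features non-excluded in *all* subjects (partial-presence
features are reported with their subject count, not silently dropped).

mpMAE includes the reference among the instances (with 4 levels × 10
replicates: 41 instances, 820 pairs). The within-level score pools all
same-level pairs (pair-weighted; equal to the unweighted per-level mean
when replicates are balanced; 4×45 = 180 pairs in the full
configuration). Ranks are fractional (ties share the mean positional
rank), which keeps Spearman correlations well-defined under ties.
Cross-subject comparisons use ranks only — frame counts differ between
subjects, so raw curves are never compared across subjects. Consensus
order: median rank ascending, ties broken by median mpMAE, then by
feature id; a parallel consensus is computed from within-level ranks.

For the ROI mean feature the pipeline admits a closed form that serves
as an analytic end-to-end check: with noise std σ and frame ROI sizes
N_t, the expected within-level pairwise MAE after normalization is
(2σ)/(√π σ_ref) · (1/T) Σ_t N_t^{−1/2}; the empirical score over 190
pairs (20 replicates) matches within 5%.

## Designed rank-recovery battery

To verify that the ranking machinery recovers a known stability order,
a battery of four synthetic features amplifies the noise deviation of
the ROI-mean curve by multipliers m = 1, 2, 4, 8:
`battery_m = ref + m·(instance − ref)`. Because the reference curve (and
hence the normalization) is shared, mpMAE scales exactly linearly in m.
A literal scaled copy m·curve would be useless here: the
reference-anchored normalization divides the scale back out, leaving all
four features identical.

## Decision-tree validation

Subjects are split per class into train/validation/test with exact,
seeded counts (default 12/4/4 per class for a 100-subject, five-class
cohort). Rows are normalized curves uniformly subsampled to 12 frames
(indices round-half-up of j(T−1)/(k−1), endpoints always included,
strict monotonicity asserted). Training and validation use all noise
instances of their subjects; the test set uses only the noise-free
curves — accuracy then measures transfer of a noise-augmented model back
to clean data. Leakage between partitions is asserted, not assumed.
Trees use Gini impurity, max depth 30, min 20 samples to split and min 7
per leaf (the classic recursive-partitioning defaults); cost-complexity
pruning has no exact scikit-learn equivalent and is left off. Features
reaching validation accuracy ≥ 1/3 count as informative; the
stability–usefulness link is the Spearman correlation between consensus
rank and test accuracy over informative features, with the median test
accuracy of the most/least stable informative features (group size 15,
clipped to half the informative count so the groups never overlap).
Validation accuracy is scored per row (per noise instance), not per
subject by majority vote.

## Problem sizes

The default test suite and the acceptance script run desk-scale studies
chosen to keep full runs in the minutes range on one CPU: a 24-frame
phantom with 4 levels × 5 replicates under full 168-feature extraction;
a six-subject heterogeneous cohort at 3 replicates for the consistency
matrix; a five-subject cohort × 20 seeds for rank recovery; a
40-subject five-class cohort (8 per class, split 4/2/2) with a reduced
filter set for the tree stage. These sizes are the package's default
study conditions; all counts are configurable up to the full 4 × 10
replicate design.

## Known limitations

- The LBP code map's noise response depends on the ratio of local clean
  image gradients to the noise amplitude. On this phantom's smooth
  texture, per-pixel gradients are comparable to std 0.01, so neighbour
  comparisons flip freely: LBP-filtered *texture-matrix* features are
  still markedly more noise-robust than their raw-image counterparts
  (the bounded discrete code range damps the response), but first-order
  summaries of the code map can be *less* stable than raw first-order
  features. Reports of LBP features being exactly noise-invariant on
  real data are not reproduced here and plausibly reflect stronger
  inherent image gradients or implementation-specific quantization.
- mpMAE magnitudes depend strongly on σ_ref: a feature whose reference
  curve is almost flat gets a huge normalized score even under mild
  noise. The long upper tail of the mpMAE distribution is therefore
  expected and is why rankings, not raw scores, are compared across
  subjects.
- Gaussian noise only; Rician magnitude statistics, segmentation
  variability under noise, and cross-scanner harmonization are out of
  scope.
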