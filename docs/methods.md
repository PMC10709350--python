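# Methods

This note documents the models, numerical choices, and limitations of
`flairmatch` at the level a maintainer or reviewer needs. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The symmetry group and its realization

Axial stroke MRI is acquired as thin slices on a square in-plane matrix, so
the exact symmetries of the voxel grid are the in-plane quarter-turn
rotations and mirror together with the through-plane flip: the point group
D4h, of order 16. The package fixes these conventions:

* volumes are `(x, y, z)`; rotations/mirror act in `(x, y)`, the flip on `z`;
* an element is `(r, m, z)` with canonical index `r + 4m + 8z`;
* `compose(g, h)` = "apply `h` first, then `g`".

The Cayley table is **derived, not hardcoded**: every element is realized as
a voxel permutation of a reference grid, products are matched back to
elements, and all group axioms (Latin square, inverses, associativity over
all 16³ triples) are verified at construction. Any consistent axis convention
yields the same group up to relabeling; fixing one makes serialized
checkpoints portable, and each checkpoint embeds the Cayley table as JSON so
a load can verify it was produced under the same convention.

## Equivariant layers

Lifting and group convolutions follow the regular-representation
construction: base kernels are stored once and *expanded at forward time* by
applying each group element's voxel permutation (plus, in group layers, the
permutation `h → g⁻¹h` of the input-orientation axis). Because expansion is
an exact permutation (no interpolation), layer equivariance holds to
float32 rounding, which the tests assert at 1e-5 and the full-network
invariance at 1e-4. Consequences of this design:

* kernels must be odd-sized with square in-plane extent;
* biases are shared across orientations (anything else breaks equivariance);
* a G-layer has exactly the parameter count of a plain convolution on the
  unfolded channels — weights are shared, not replicated;
* 2×2×2 max pooling is exactly equivariant only when the pooled dims are
  even. On grids divisible by 2^stages (the 64×64×32 desk grid with up to
  5 stages) invariance is exact; on the 192×192×50 clinical grid the odd
  z-dimension after stage 1 makes z-flip equivariance approximate. This is
  documented rather than fixed, since the clinical grid is fixed by the
  acquisition.
* orientation pooling (max) happens once, immediately before global average
  pooling, keeping oriented features through all stages.

## Architecture

All models share one encoder recipe: per stage a convolution (lifting first,
then group convolutions when `equivariant=True`; plain 3D convolutions
otherwise), LeakyReLU(0.1), and 2×2×2 max pooling. The head is orientation
pool → global average pool → two fully connected ReLU layers → dropout → one
linear unit; the sigmoid lives in the loss and `predict_proba`, so training
and saliency operate on the logit. The baseline CNN and the G-CNN accept
identical configurations; `equivariant` is the only switch.

The five-stage clinical-scale configuration (channels 8-16-32-64-128, input
192×192×50×2) exists and is shape-checked in the tests, but the package's
working default is a **desk-scale** configuration chosen so the whole study
runs on one CPU core in minutes:

* input block-averaging `input_pool=(8, 8, 4)` (64×64×32 → 8×8×8). Block
  averaging commutes with every D4h action on divisible grids, so exact
  invariance is preserved; it also suppresses voxel noise before the first
  convolution.
* two stages, channels (6, 12), 3×3×3 kernels, head widths (16, 8), no
  dropout (the desk model is small enough not to need it).

Three optimization-stability choices deserve explanation, because plain
SGD on small cohorts otherwise converges to the constant-prevalence
predictor (the head weights shrink to zero, which freezes encoder gradients
permanently):

1. **LeakyReLU in conv stages** keeps gradient flowing through units below
   threshold, so a collapsed feature can recover.
2. **Negative conv-bias initialization** (−0.5): lesions occupy ~1 % of the
   volume, and a sub-zero ReLU threshold at initialization makes activations
   sparse, so global pooling sees focal detector responses instead of
   diluted background.
3. **Mismatch-detector initialization** (`mismatch_init`): the first two
   stage-1 filters start as a center-voxel DWI−FLAIR difference and a
   DWI-only detector — the two contrasts the clinical sign is defined by —
   with all remaining filters random. This is the same spirit as
   Gabor-initialized first layers in natural-image CNNs: it removes the
   constant-prediction basin without constraining what training learns.
   The identical initialization is applied to the plain-CNN baseline, so
   the equivariance comparison stays architecture-matched.

The autoencoder variants: the CAE keeps the encoder, adds a 1×1×1 bottleneck
convolution, and mirrors the stages with nearest-neighbour upsampling +
convolution (chosen over transposed convolution to avoid checkerboard
artifacts), ending in a crop/pad to the exact input shape; odd dimensions
under halving use floor. The AE-regularized model shares the encoder between
the classification head and the decoder and combines losses as
`L = α·L_bc + (1−α)·L_mse` (default α = 0.5 when regularizing; α = 1 recovers
the pure classifier). Encoder weights transfer between CAE and classifier by
name; incompatible checkpoints fail with a per-layer shape diff.

## Training protocol

* SGD with Nesterov momentum (defaults lr 1e-2, momentum 0.9); epochs and
  batch size are configuration.
* Class-weighted BCE with `w_c = N_total/(2 N_c)`; the weighted class masses
  balance exactly (`w0·N0 = w1·N1 = N_total/2`). The loss is computed on
  logits in the stable `logaddexp` form; the public `weighted_bce` on
  probabilities clamps at 1e-7.
* 4-fold cross-validation, ratios 56/19/25 with floor rounding and the
  remainder assigned to training — for 489 patients this gives four disjoint
  122-patient test folds. Splits are deterministic in the seed; an optional
  stratified mode applies the same scheme per class (the pipeline uses it,
  since desk-scale validation sets are small enough to go single-class).
* Model selection keeps the best validation-loss checkpoint; optional early
  stopping with configurable patience (training loops never see test data —
  the interfaces take explicit validation arrays only).
* One master seed fans out to split/shuffle/dropout/noise streams
  (`numpy` `SeedSequence`); two runs with the same seed produce identical
  weights.

## Evaluation protocol

* AUC is the Mann-Whitney probability (ties 0.5), computed by scikit-learn
  and cross-checked in the tests against an O(n²) pair-counting oracle.
* Candidate thresholds are midpoints of consecutive sorted unique scores
  plus sentinels — a finite, complete search space. The Youden threshold
  maximizes sens+spec−1 (ties toward the more specific cut). Sensitivity
  calibration returns the **largest** threshold whose *validation*
  sensitivity ≥ target (default 0.62, the multicenter human benchmark),
  applied unchanged to test scores. Binary-call convention everywhere:
  `score ≥ threshold` ⇒ class 1 (≤ 4.5 h).
* Indeterminable ratings count as "> 4.5 h" (such patients would be excluded
  from thrombolysis); augmentation substitutes the model's call for exactly
  the indeterminable ratings and touches nothing else.
* Cohen's κ is computed on binary calls after that mapping (a switch
  provides 3-category κ, since it is a defensible alternative reading).
  Degenerate case: both raters constant and identical ⇒ κ := 1 with a
  warning; a single constant rater gives κ = 0.
* Significance: paired bootstrap — subsets of N = 200 patients drawn with
  replacement, the *same* indices applied to both rating schemes — followed
  by a two-sided Wilcoxon signed-rank test on the paired metric values
  (zero differences dropped; SciPy's exact distribution for small tie-free
  samples, tie-corrected normal approximation otherwise). The repetition
  count doubles from its initial value until the mean bootstrap metric of
  each scheme is within 0.01 of its full-set value. Significance level 0.05.

## SmoothGrad explanations

Saliency is the mean absolute input-gradient of the **pre-sigmoid logit**
(gradients of the probability vanish for confident cases) over `n` noisy
copies, noise std = `sigma ×` input intensity range; defaults n=25,
sigma=0.1 follow common SmoothGrad practice, and `sigma=0, n=1` reduces
bit-for-bit to the plain gradient. Heatmaps are per-channel max-normalized
before a single universal threshold (default 0.3, chosen by inspecting a few
example phantoms; configuration) is applied to all patients. Localization
against the known phantom lesion mask reports lesion coverage and Dice per
channel; "well-localized" = coverage > 0.5 on DWI and on the same region in
FLAIR. This is an automated surrogate for visual heatmap rating, not a
reproduction of it.

## The phantom generator

The generator reproduces the statistical structure the classifier exploits,
not anatomy: a smoothed Gaussian random field plus a ventricle-like central
structure (dark on DWI, bright on FLAIR), an ellipsoidal acute lesion
(in-plane radius 5–10 voxels, through-plane 2.5–5 on the 64×64×32 grid) with
fixed DWI contrast 1.2 and FLAIR contrast `sigmoid((t − 4.5)/2.0)` — the
monotone conspicuity curve with its midpoint at the treatment boundary, so
the label boundary is the hardest region, as in the clinic. Gaussian voxel
noise (σ = 0.15) is added to both channels. Onset times are drawn by class
(acute fraction 0.4335, the labeled clinical cohort's prevalence) uniformly
within [0.5, 4.5] or (4.5, 24] hours. Confounders: leukoaraiosis-like
periventricular FLAIR hyperintensity (rate 0.3, independent of onset time),
FLAIR-bright/DWI-silent old lesions (0.2), and small bright DWI artifacts
(0.2). The unlabeled cohort is distribution-shifted: 40 % lesion-free, 25 %
with lesions in a different z-band, onset time unrecorded.

Synthetic raters call mismatch/no-mismatch with configured sensitivity and
specificity against the true label; a configured fraction of patients —
sampled with weight inversely related to FLAIR lesion contrast, i.e. the
genuinely ambiguous cases — is rated indeterminable.

What passing tests on phantoms do **not** show: robustness to real scanner
variability, registration error (phantoms are coregistered by construction;
the resampling backend is exercised separately), pathology diversity, or the
clinical difficulty level — phantom AUCs are far above what is achievable on
real cohorts, because the mismatch signal here is clean by design. The
phantoms validate the *machinery* (equivariance, calibration, augmentation
statistics), not clinical performance.

## Problem sizes

The package's own experiments use 200 labeled phantoms at 64×64×32 with a
150/50 train/validation split for the learning study (three seeds per
architecture), 16×16×8 or 64×64×32 grids for equivariance/invariance checks,
and n = 500 rating vectors with N = 200 bootstrap subsets for the
significance machinery — sizes chosen so the full suite runs on a single CPU
core in a few minutes while every statistical conclusion still has adequate
power.

## Known limitations

* No GPU path; the NumPy implementation is practical at desk scale only.
* Deformable registration is out of scope; `coregister_resample` offers an
  identity backend and an affine-resampling backend.
* Dropout placement follows the published architecture sentence (after the
  second fully connected layer); no batch/instance normalization is used.
* The bottleneck/decoder widths, fully connected widths, and dropout rate of
  the original clinical model are not public; all are configuration with the
  defaults above.
* Exact invariance requires spatial dims divisible by 2^stages; otherwise
  invariance is approximate (floor-cropped pooling).
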