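# Methods

This note documents the generative model, the training scheme, the numerical
choices, and what the synthetic test world does and does not establish.

## Generative model

A training sample is a pure function of `(label map, GeneratorConfig, seed)`.
Stages, in order:

1. **Lesion insertion** (probability `lesion_prob`, default 0.5): one mask
   from the lesion bank, rigidly placed (random axis permutation/flip plus
   integer translation), painted only over cerebral labels; placements with
   empty cerebral overlap are resampled up to 10 times, then skipped. One
   insertion per sample. The lesioned map conditions the *input* only; the
   target and the segmentation labels come from the clean map, so the
   network is trained to inpaint.
2. **Geometric augmentation**, shared by the clean and lesioned maps so the
   pair stays aligned: a random affine (rotation ±15° per axis, scale
   0.85–1.15, shear ±0.012, translation ±5 mm) composed with a diffeomorphic
   warp and applied in a single nearest-neighbor resampling pass. The warp
   is the exponential of a stationary velocity field: i.i.d. Gaussian
   velocities on a control grid with 10-voxel spacing, rescaled so the
   maximum velocity magnitude equals a per-sample amplitude ~ U(0, 3)
   voxels, linearly upsampled, and integrated by scaling-and-squaring with
   7 steps. The squaring compositions use cubic interpolation — linear
   sampling leaves ~0.14-voxel inverse-consistency residuals at amplitude 3,
   cubic ~0.08. The coarse grid doubles as the smoothing scale; at these
   defaults the integrated fields have strictly positive Jacobians and
   invert to < 0.1 voxel residual (both tested over 100 seeds).
3. **Contrast**: per-label `mu ~ U(0, 1)`, `sigma ~ U(0, 0.1)`; voxel
   intensities i.i.d. `N(mu_label, sigma_label²)`. Because all labels share
   one range, contrast inversions (T2-like) are as likely as T1-like
   orderings — the premise of domain randomization.
4. **Bias field**: exp of a trilinearly upsampled 4³ Gaussian log-field,
   log-amplitude ~ U(0, 0.4). **Noise**: additive Gaussian, sd ~ U(0, 0.08)
   (Rician optional, off by default). Bias is applied before noise (coil
   sensitivity, then thermal noise).
5. **Acquisition**: one axis per sample (2D clinical acquisitions), spacing
   ~ U(1, 9) mm (covering the 5–7 mm clinical regime), thickness
   ~ U(1, spacing). The slice value at center c is the signal integrated
   against a Gaussian profile of FWHM = thickness; because the signal is
   piecewise constant over 1-mm voxels, the integral is computed exactly
   with erf differences over voxel extents (a boxcar profile is available).
   Slices are then linearly interpolated back to the 1-mm grid, so input
   and target live in the same voxel space. The whole operator is linear
   and is validated against an independent adaptive-quadrature oracle.
6. **Normalization**: input min-max to [0, 1]; target scaled so the mean
   white-matter intensity is exactly 1.0.

The spec-level ordering `degrade(corrupt(synthesize(...)))` is implemented
literally: noise is added at high resolution and then blurred by the slice
profile. Ranges that the original method leaves unstated (all of the above
defaults) are configuration, not claims, and live in `GeneratorConfig`
(YAML round-trippable).

## Label phantoms

Real training anatomy (manually labeled whole-head maps) cannot ship with
the repository, so `generate_phantom_labels` builds a parametric stand-in:
perturbed concentric ellipsoids — background, extracerebral shells, cortical
ribbon, white matter, deep-gray blobs, a central ventricle. The boundary
wiggle is a smoothed Gaussian field scaled *proportionally to the radius*,
so small central structures keep their volume while outer boundaries deform
freely. Every requested class is guaranteed ≥ 0.1% of voxels. Real label
maps are accepted via NIfTI with a JSON sidecar table. The phantom is not
anatomically faithful (no cortical folding, no atlas numbering); what it
preserves is what the generator relies on: a designated white-matter class,
a cerebral/extracerebral split, smooth curved interfaces, and a rare small
class (ventricle) that exercises class-imbalance behavior.

The reference (target) image is a canonical T1-like rendering: white matter
1.0, gray matter ~0.6, CSF ~0.15, with small deterministic per-code offsets
so classes remain distinguishable, plus optional low-amplitude texture
noise (sd 0.02). This replaces the real 1-mm MPRAGE that the original
pipeline regresses to.

## Networks and losses

Both U-nets share the encoder/decoder: five resolution levels (two 3×3×3
convolutions + ELU per level), 24 features at the first level, doubled after
each 2×2×2 max pooling and halved after each upsampling, skip connections by
concatenation; the regression head is a linear 1×1×1 convolution with one
feature, the segmentation head a K-feature convolution with channel softmax.
No normalization layers or dropout. He initialization from a seeded RNG.

Deviation from an earlier design sketch: decoder upsampling is
**nearest-neighbor**, not trilinear. The networks are implemented in plain
numpy with hand-written backward passes (no deep-learning framework in the
runtime environment), and the adjoint of nearest upsampling is exact block
summation; trilinear would buy marginal smoothness for significantly more
error-prone adjoint code. Convolutions use im2col views + BLAS tensordot,
float32 throughout; gradients are verified against finite differences.

The objective is `L = Lreg + lambda * Lseg`, `lambda = 0.25`. `Lreg` is the
L1 norm of the intensity error; the printed form is a sum over voxels, but
the *optimized* quantity is the per-voxel mean, so that `lambda` transfers
across patch sizes (the sum is also logged). `Lseg = 1 − soft Dice` between
the one-hot labels and the frozen segmenter's probabilities, averaged over
classes, smoothing `eps = 1e-5`. With `lambda = 0` the gradient path through
the segmenter is skipped entirely, so the trajectory is bit-identical to a
regression-only run (tested).

**Segmenter pretraining** minimizes soft Dice *plus an inverse-frequency-
weighted cross-entropy term*. Dice alone cold-starts badly on rare classes:
a class the softmax never predicts receives a vanishing Dice gradient and
can stay at zero forever (observed for the phantom ventricle, ~0.3% of
voxels). The weighted CE term keeps every present class learning; held-out
mean soft Dice on noise-free phantoms exceeds 0.9 after ~500 desk-scale
iterations. The segmenter is then frozen: the main loop backpropagates
*through* it into the regression output but never updates it (checksum
verified before/after).

**Optimization**: Adam. Full-scale reference values — lr 1e-4, 250,000
iterations, roughly two GPU-weeks — are documented but are not a repository
target. The desk-scale preset (3-level, 8-feature net, 32³ volumes, batch 1,
300 iterations) uses lr 1e-3, the customary Adam default for small networks;
at 300 iterations a 1e-4 step size cannot move the output head to the
target's intensity scale, so 1e-4 is meaningful only at full scale. Every
random draw in training derives from the run seed; fixed seed and thread
count reproduce the loss trajectory bitwise. A non-finite loss aborts with
the offending sample seed.

## Inference

Preprocessing is exactly what the network expects and nothing else: reorient
to RAS, trilinearly resample to 1 mm isotropic (skipped when already
conformed), zero-pad each axis up to the *next* multiple of 32 (required by
five levels of halving; rounding down would crop anatomy — "closest
multiple" is resolved as round-up, split symmetrically), min-max normalize.
The inverse bookkeeping (`PreprocMeta`) restores the unpadded 1-mm grid.
Output intensities stay in model units ([0, 1] training scale); a `--rescale`
flag multiplies by a user factor. Inputs with more than three dimensions are
rejected (and skipped with a warning in batch mode).

## Evaluation statistics

- **Volume agreement**: per-ROI Pearson r between predicted and reference
  volume tables, at scan level or subject level (median across a subject's
  scans, hence invariant to scan multiplicity).
- **Covariate correction**: volumes minus the least-squares fit on ICV and a
  two-level sex indicator, plus the grand mean; residuals are exactly
  orthogonal to the covariates.
- **Age trajectories**: `y | age ~ Laplace(m(age), s(age))` with `m` and
  `log s` cubic B-splines on six knots placed at equally spaced age
  quantiles (clamped boundary). The likelihood is maximized by L-BFGS on a
  smoothed objective (`|r| -> sqrt(r² + eps²)`, `eps = 1e-6`) with analytic
  gradients and multi-start (3 perturbed restarts). The 95% band is a delta-
  method band using the Laplace location Fisher information `1/s²` per
  observation. On data simulated from a known model (n = 2000) the median
  curve is recovered to < 2% relative integrated error and the band covers
  the truth 90–99% of the time over 200 replicates.
- **Group comparison**: exact medians; two-sided Wilcoxon rank-sum p
  (delegated to `scipy.stats.mannwhitneyu`); AUROC from the rank-sum
  statistic with average ranks, which equals exhaustive pair enumeration
  including ties (verified for all group sizes up to 50). Shapiro–Wilk is a
  thin pass-through to scipy.

## Synthetic cohorts

`make_cohort` draws subjects with uniform ages, random sex, and phantom
geometry modulated by an atrophy rule (`linear`: ventricles enlarge,
cortex thins with age) to emulate the disease/aging shape effects the
synthesis must preserve. ICV is the cerebral voxel count. `make_eval_tables`
produces matched truth/predicted volume tables with planted noise and bias
for calibrating the evaluation statistics against known ground truth.

## What a green test establishes — and what it does not

The phantom world validates the *mechanics*: generator identity limits,
oracle agreement of the partial-volume operator, diffeomorphism of the
augmentation, loss arithmetic, freezing and ablation contracts, the
inference grid contract, statistical calibration, and that desk-scale
domain-randomized training learns enough to beat the interpolation baseline
on held-out synthetic samples. It does *not* establish clinical-grade
synthesis quality: phantoms lack cortical folding and real tissue texture,
the reference rendering is not a real MPRAGE, desk-scale networks are far
smaller than the full-scale model, and no claim about real-scanner data
follows from these tests.

## Known limitations

- Training is CPU-bound numpy; full-scale replication is out of scope.
- Degradation applies along exactly one axis per sample; 3D acquisitions
  with two coarse axes are not simulated.
- The lesion model is a single rigid placement of bank masks; registration
  of real lesion libraries to each subject is not implemented.
- Continuous pathology gradients (e.g., infiltrating tumor) are outside the
  label-based appearance model.
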