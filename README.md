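# isosynth

Domain-randomized synthesis of 1-mm isotropic T1-weighted brain MRI from
scans of **any orientation, resolution and contrast** — plus the generative
training scheme that makes it possible, and the evaluation statistics for
validating it on volumetric cohorts.

## The problem

Most research neuroimaging tools (cortical surface reconstruction,
subcortical segmentation, registration) assume ~1-mm isotropic T1-weighted
input. Clinical brain MRI is nothing like that: 2D acquisitions with 20–30
slices, 5–7 mm slice spacing, arbitrary orientation, and whatever contrast
the radiologist ordered. `isosynth` implements a *synthesis-by-domain-
randomization* approach: instead of training an image-translation network on
paired real scans (which never cover the clinical variety), training data
are **simulated from anatomical label maps** with fully randomized nuisance
parameters, so the network never sees the same contrast, resolution, bias
field or noise level twice and learns to ignore them all.

## The model

From a label map `L` the generator draws, per training sample:

- a random **per-label Gaussian contrast**: `mu_k ~ U(0,1)`, `sigma_k ~ U(0,0.1)`,
  so over training every MR contrast (T1-like, T2-like, anything between)
  is produced;
- a shared **geometric augmentation**: random affine plus a diffeomorphic
  warp (stationary velocity field, exponentiated by scaling-and-squaring);
- a smooth multiplicative **bias field** and additive **noise**;
- a random **acquisition geometry**: axis (sagittal/coronal/axial), slice
  spacing `~ U(1, 9)` mm, slice thickness `~ U(1, spacing)` mm, modeled as a
  Gaussian slice-profile blur (FWHM = thickness, erf-integrated over voxel
  extents) followed by slice subsampling and linear interpolation back to
  the 1-mm grid;
- optionally a **lesion label** painted into cerebral tissue — present in
  the input but absent from the target, so the network learns to inpaint
  pathology with healthy-looking tissue.

The input is min-max normalized to [0,1]; the target is the clean reference
rendering with mean white-matter intensity matched to 1.0. Two 3D U-nets
(five levels, two 3×3×3 ELU convolutions per level, 24 base features doubled
per level) are trained as

```
L(theta) = ||Y - f(X; theta)||_1  +  lambda * (1 - DICE[L_y, SEG(f(X; theta))])
```

with `lambda = 0.25`: an L1 regression loss plus a soft-Dice loss through a
**frozen, pre-trained segmentation U-net**, which sharpens the synthesis so
that downstream segmentation tools behave well. Optimization is Adam; the
full-scale reference schedule is lr 1e-4 for 250k iterations, while the
repository's desk-scale preset (small net, 32³ phantoms, lr 1e-3, a few
hundred iterations, CPU-only numpy implementation) trains in minutes.

Because no deep-learning framework is assumed, the U-nets, their backward
passes and Adam are implemented in pure numpy (`isosynth.nn`).

## Worked example

```python
import numpy as np
from isosynth import (GeneratorConfig, generate_phantom_labels,
                      make_training_sample, train_synthsr, synthesize_t1)
from isosynth.losses import LossConfig
from isosynth.training import OptimConfig, heldout_l1

cfg = GeneratorConfig()                     # all randomization ranges
labels = lambda s: generate_phantom_labels((32, 32, 32), 6, 3, seed=s % 50)

state, log = train_synthsr(labels, cfg, loss_cfg=LossConfig(lam=0.0),
                           optim=OptimConfig(learning_rate=1e-3,
                                             n_iterations=300, seed=0))
print(f"loss: {log.loss.head(20).mean():.4f} -> {log.loss.tail(20).mean():.4f}")

rng = np.random.default_rng(777)
samples = [make_training_sample(labels(1000 + i), cfg,
                                seed=int(rng.integers(2**31 - 1)))
           for i in range(20)]
df = heldout_l1(state, samples)
print(f"held-out mean L1: model {df.l1_model.mean():.3f} "
      f"vs interpolation baseline {df.l1_baseline.mean():.3f}, "
      f"wins {(df.l1_model < df.l1_baseline).sum()}/20")
```

prints (single CPU, ~3 minutes):

```
loss: 0.2142 -> 0.1314
held-out mean L1: model 0.133 vs interpolation baseline 0.433, wins 20/20
```

i.e. after 300 domain-randomized iterations the small regression net already
reconstructs the clean target three times more accurately (in mean absolute
intensity error, white-matter-normalized units) than passing the degraded
input through unchanged, on all 20 held-out random-contrast samples.

Inference on any NIfTI volume, given a trained checkpoint:

```bash
isosynth --i clinical_scan.nii.gz --o synthetic_t1.nii.gz --ckpt ckpt/regression.npz
```

The output is always on a 1-mm isotropic RAS grid covering the input field
of view; the only preprocessing is resampling, padding to a multiple of 32,
and min-max normalization — no skull stripping or bias-field correction.

Companion commands: `isosynth-phantom` (label phantoms), `isosynth-generate`
(training triplets + manifest), `isosynth-train` (desk-scale training),
`isosynth-fixtures` (phantom cohorts with demographics).

## Evaluation module

`isosynth.evaluation` implements the statistics used to validate synthetic
volumetry: per-ROI Pearson agreement at scan or subject (median) level, ICV
and sex residualization, robust age-trajectory regression (Laplace
likelihood with spline location and scale, six knots), Wilcoxon rank-sum
tests and AUROC for group separation, and Shapiro–Wilk normality checks.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — phantom generation,
the domain-randomized generator, a short desk-scale training run, inference,
and the evaluation statistics on a synthetic cohort — and writes the results
JSON to `--out`.
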