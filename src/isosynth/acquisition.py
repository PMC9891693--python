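"""Clinical acquisition geometry: slice thickness, spacing and orientation.

A 2D clinical acquisition excites slabs of finite thickness (partial volume:
tissues mix within the slab) at centers separated by the slice spacing, with
high in-plane resolution.  We model this along a single axis of the 1-mm
isotropic generator grid:

1. partial volume — each slice value is the input signal (piecewise constant
   over 1-mm voxels) integrated against a slice profile centered on the
   slice: Gaussian with FWHM = thickness (erf-integrated over voxel extents,
   so the quadrature is exact), or an optional boxcar;
2. subsampling — slice centers every ``spacing`` mm;
3. back-interpolation — linear interpolation onto the original 1-mm grid, so
   input and target always live in the same voxel space.

All three stages are linear, so ``degrade`` is a linear operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import erf

from .augment import integrate_svf, sample_affine, sample_velocity_field, warp
from .config import GeneratorConfig
from .contrast import (
    BiasFieldParams,
    corrupt,
    minmax01,
    normalize_target,
    sample_bias_field,
    sample_gmm,
    synthesize,
)
from .phantom import LesionBank, insert_lesion, wm_code_of
from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "AcquisitionParams",
    "TrainingSample",
    "sample_acquisition",
    "degrade",
    "canonical_reference",
    "make_training_sample",
]

AXES = ("sagittal", "coronal", "axial")  # volume axes 0, 1, 2 on a RAS grid
_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AcquisitionParams:
    axis: str            # one of AXES
    spacing: float       # mm between slice centers
    thickness: float     # slab FWHM, mm (0 = ideal delta profile)
    in_plane: float = 1.0

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")

    @property
    def axis_index(self) -> int:
        return AXES.index(self.axis)


def sample_acquisition(
    spacing_range: tuple[float, float] = (1.0, 9.0),
    thickness_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> AcquisitionParams:
    """Uniform axis; spacing ~ U(spacing_range); thickness ~ U(min(1, spacing), spacing)
    unless an explicit thickness_range overrides the default rule."""
    lo, hi = spacing_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid spacing range")
    rng = np.random.default_rng(seed)
    axis = AXES[rng.integers(3)]
    spacing = float(rng.uniform(lo, hi))
    if thickness_range is None:
        t_lo = min(1.0, spacing)
        thickness = float(rng.uniform(t_lo, spacing))
    else:
        thickness = float(rng.uniform(*thickness_range))
    return AcquisitionParams(axis, spacing, thickness)


def _profile_weights(n: int, centers: np.ndarray, thickness: float, profile: str) -> np.ndarray:
    """(n_slices, n) matrix of normalized slice-profile weights.

    Weight of voxel i (support [i-1/2, i+1/2]) for a slice at center c is the
    integral of the profile over the voxel extent — the exact partial-volume
    contribution of a piecewise-constant signal.
    """
    edges_lo = np.arange(n) - 0.5
    edges_hi = edges_lo + 1.0
    c = centers[:, None]
    if thickness < 1e-6:
        # delta profile: nearest voxel
        idx = np.clip(np.rint(centers).astype(int), 0, n - 1)
        W = np.zeros((len(centers), n))
        W[np.arange(len(centers)), idx] = 1.0
        return W
    if profile == "gaussian":
        sd = thickness * _FWHM_TO_SD
        z = 1.0 / (sd * np.sqrt(2.0))
        W = 0.5 * (erf((edges_hi - c) * z) - erf((edges_lo - c) * z))
    elif profile == "boxcar":
        half = thickness / 2.0
        W = np.clip(np.minimum(edges_hi, c + half) - np.maximum(edges_lo, c - half), 0, None)
    else:
        raise ValueError(f"unknown slice profile {profile!r}")
    # renormalize over the field of view so constants are preserved exactly
    W = W / W.sum(axis=1, keepdims=True)
    return W


def _linear_interp_matrix(n: int, centers: np.ndarray) -> np.ndarray:
    """(n, n_slices) matrix interpolating slice values back to the 1-mm grid."""
    B = np.zeros((n, len(centers)))
    x = np.arange(n, dtype=float)
    for j in range(n):
        pos = x[j]
        if pos <= centers[0]:
            B[j, 0] = 1.0
        elif pos >= centers[-1]:
            B[j, -1] = 1.0
        else:
            k = int(np.searchsorted(centers, pos, side="right")) - 1
            k = min(k, len(centers) - 2)
            t = (pos - centers[k]) / (centers[k + 1] - centers[k])
            B[j, k] = 1.0 - t
            B[j, k + 1] = t
    return B


def degrade(
    hr: IntensityVolume, acq: AcquisitionParams, profile: str = "gaussian"
) -> IntensityVolume:
    """Slice-profile blur + subsample + linear back-interpolation along one axis."""
    vox = hr.voxel_sizes()
    if not np.allclose(vox, 1.0, atol=1e-3):
        raise ValueError(f"degrade expects a 1-mm isotropic volume, got voxels {vox}")
    ax = acq.axis_index
    n = hr.shape[ax]
    centers = np.arange(0.0, n - 1 + 1e-9, acq.spacing)
    if len(centers) < 2:
        raise ValueError(
            f"spacing {acq.spacing} mm leaves fewer than two slices in a "
            f"{n}-mm field of view"
        )
    W = _profile_weights(n, centers, acq.thickness, profile)
    B = _linear_interp_matrix(n, centers)
    M = B @ W  # (n, n) combined operator along the acquisition axis
    data = np.moveaxis(hr.data, ax, 0)
    out = np.tensordot(M, data, axes=(1, 0))
    out = np.moveaxis(out, 0, ax)
    return IntensityVolume(out, hr.affine.copy(), "raw")


# ---------------------------------------------------------------------------
# Full generative pipeline
# ---------------------------------------------------------------------------

# canonical T1-like (MPRAGE) brightness per label role, white matter = 1.0
_CANONICAL = {
    "background": 0.02,
    "extracerebral": 0.45,
    "cerebral": 0.62,
    "white-matter": 1.0,
    "ventricle": 0.15,
    "cortex": 0.62,
}


def canonical_reference(
    labels: LabelVolume, noise_sd: float = 0.02, seed: int = 0
) -> IntensityVolume:
    """Render a fixed MPRAGE-like reference from labels (the regression target).

    Stands in for a real 1-mm T1-weighted scan: white matter brightest,
    gray matter intermediate, CSF dark.  Per-code means get a small
    deterministic offset so distinct classes remain distinguishable.
    """
    means = {}
    for code, entry in labels.label_table.items():
        base = _CANONICAL.get(entry.name, _CANONICAL.get(entry.role, 0.5))
        if entry.name.startswith("deep-gray"):
            base = 0.55
        if entry.name.startswith("extracerebral"):
            base = 0.35 + 0.18 * (code % 3)
        if entry.role == "lesion":  # references are pathology-free; value unused normally
            base = 1.0
        # deterministic per-code jitter keeps classes distinct
        means[code] = base + 0.013 * (code % 5)
    sds = {c: noise_sd for c in means}
    from .contrast import GMMParams  # local import avoids a cycle at module load

    return synthesize(labels, GMMParams(means, sds), seed=seed)


@dataclass
class TrainingSample:
    """One paired draw: degraded random-contrast input, clean target, labels."""

    x: IntensityVolume        # minmax01, 1-mm grid
    y: IntensityVolume        # wm1 units, same grid
    labels: LabelVolume       # lesion-free deformed labels (segmentation target)
    meta: dict[str, Any] = field(default_factory=dict)


def make_training_sample(
    labels_clean: LabelVolume,
    config: GeneratorConfig,
    seed: int = 0,
    lesion_bank: LesionBank | None = None,
    reference: IntensityVolume | None = None,
) -> TrainingSample:
    """One full domain-randomized draw.

    The clean and lesioned label maps are deformed with the SAME transform;
    the input X is synthesized from the lesioned map (lesions are just extra
    ROIs with their own random contrast), the target Y from the clean map —
    so the network learns to inpaint pathology with healthy-looking tissue.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, 12)

    # 1. lesion insertion on a copy of the clean labels
    labels_lesion = labels_clean
    if lesion_bank is not None and config.lesion_prob > 0:
        labels_lesion = insert_lesion(
            labels_clean, lesion_bank, config.lesion_prob, config.lesion_code,
            seed=int(seeds[0]),
        )

    # 2. one shared geometric augmentation for both label maps
    affine = None
    field_ = None
    if max(config.rot_range, config.scale_range, config.shear_range, config.trans_range) > 0:
        affine = sample_affine(
            config.rot_range, config.scale_range, config.shear_range,
            config.trans_range, seed=int(seeds[1]),
        )
    if config.svf_amplitude > 0:
        v = sample_velocity_field(
            labels_clean.shape, config.svf_amplitude, config.svf_spacing,
            seed=int(seeds[2]),
        )
        field_ = integrate_svf(v, labels_clean.shape, config.svf_steps)
    if affine is not None or field_ is not None:
        labels_clean_w = warp(labels_clean, affine, field_)
        labels_lesion_w = (
            labels_clean_w if labels_lesion is labels_clean
            else warp(labels_lesion, affine, field_)
        )
    else:
        labels_clean_w, labels_lesion_w = labels_clean, labels_lesion

    # 3. input X: random contrast -> bias -> noise -> acquisition -> minmax
    present = set(int(c) for c in np.unique(labels_lesion_w.data))
    gmm = sample_gmm(present, config.mean_range, config.sd_range, seed=int(seeds[3]))
    img = synthesize(labels_lesion_w, gmm, seed=int(seeds[4]))
    bias = None
    log_amp = float(np.random.default_rng(int(seeds[5])).uniform(*config.bias_log_amplitude))
    if log_amp > 0:
        bias = sample_bias_field(
            img.shape, BiasFieldParams(config.bias_grid, log_amp), seed=int(seeds[6])
        )
    noise_sd = float(np.random.default_rng(int(seeds[7])).uniform(*config.noise_sd_range))
    img = corrupt(img, bias, noise_sd, seed=int(seeds[8]), rician=config.rician)
    acq = sample_acquisition(config.spacing_range, config.thickness_range, seed=int(seeds[9]))
    img = degrade(img, acq, profile=config.slice_profile)
    x = minmax01(img)

    # 4. target Y: pathology-free reference in white-matter-normalized units
    wm = wm_code_of(labels_clean_w)
    if reference is not None:
        ref = warp(reference, affine, field_) if (affine or field_) else reference
    else:
        ref = canonical_reference(
            labels_clean_w, config.reference_noise_sd, seed=int(seeds[10])
        )
    y = normalize_target(ref, labels_clean_w, wm)

    meta = {
        "seed": int(seed),
        "axis": acq.axis,
        "spacing": acq.spacing,
        "thickness": acq.thickness,
        "noise_sd": noise_sd,
        "bias_log_amplitude": log_amp,
        "wm_code": wm,
        "lesioned": labels_lesion is not labels_clean,
    }
    return TrainingSample(x, y, labels_clean_w, meta)
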