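"""Label-conditioned intensity synthesis and corruption.

Each anatomical class receives a random Gaussian intensity distribution
(mean and sd drawn uniformly per sample), so over training the generator
emits every conceivable MR contrast — T1-like, T2-like, and everything in
between — which is the premise that lets a single network handle arbitrary
input contrasts.  Corruption adds a smooth multiplicative bias field
(exponentiated low-resolution Gaussian log-field) and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "GMMParams",
    "BiasFieldParams",
    "sample_gmm",
    "synthesize",
    "sample_bias_field",
    "corrupt",
    "normalize_target",
    "minmax01",
]


@dataclass
class GMMParams:
    """Per-label Gaussian intensity parameters."""

    means: dict[int, float]
    sds: dict[int, float]

    def __post_init__(self):
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same label codes")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("standard deviations must be >= 0")


@dataclass
class BiasFieldParams:
    grid: int = 4                # control nodes per axis
    log_amplitude: float = 0.3   # sd of the log-field

    def __post_init__(self):
        if self.grid < 2:
            raise ValueError("bias control grid needs >= 2 nodes per axis")
        if self.log_amplitude < 0:
            raise ValueError("log amplitude must be >= 0")


def sample_gmm(
    labels_present: set[int] | list[int],
    mean_range: tuple[float, float] = (0.0, 1.0),
    sd_range: tuple[float, float] = (0.0, 0.1),
    seed: int = 0,
) -> GMMParams:
    """Draw mu_k ~ U(mean_range), sigma_k ~ U(sd_range) independently per label."""
    codes = sorted(int(c) for c in labels_present)
    if not codes:
        raise ValueError("labels_present is empty")
    for lo, hi in (mean_range, sd_range):
        if hi < lo:
            raise ValueError("invalid range (high < low)")
    if sd_range[0] < 0:
        raise ValueError("sd range must be non-negative")
    rng = np.random.default_rng(seed)
    means = rng.uniform(*mean_range, len(codes))
    sds = rng.uniform(*sd_range, len(codes))
    return GMMParams(dict(zip(codes, means.tolist())), dict(zip(codes, sds.tolist())))


def synthesize(labels: LabelVolume, gmm: GMMParams, seed: int = 0) -> IntensityVolume:
    """Voxel intensity ~ N(mu_label, sigma_label^2), independently per voxel."""
    present = set(int(c) for c in np.unique(labels.data))
    missing = present - set(gmm.means)
    if missing:
        raise ValueError(f"no GMM parameters for label codes {sorted(missing)}")
    max_code = max(present)
    mu = np.zeros(max_code + 1)
    sd = np.zeros(max_code + 1)
    for c in present:
        mu[c] = gmm.means[c]
        sd[c] = gmm.sds[c]
    rng = np.random.default_rng(seed)
    data = mu[labels.data]
    sds = sd[labels.data]
    if np.any(sds > 0):
        data = data + rng.standard_normal(labels.shape) * sds
    return IntensityVolume(data, labels.affine.copy(), "raw")


def sample_bias_field(
    shape: tuple[int, int, int], params: BiasFieldParams, seed: int = 0
) -> IntensityVolume:
    """Smooth strictly-positive multiplicative field: exp of an upsampled log-field."""
    rng = np.random.default_rng(seed)
    log_coarse = rng.standard_normal((params.grid,) * 3) * params.log_amplitude
    coords = np.meshgrid(
        *[np.linspace(0, params.grid - 1, n) for n in shape], indexing="ij"
    )
    log_dense = ndimage.map_coordinates(log_coarse, np.stack(coords), order=1, mode="nearest")
    return IntensityVolume(np.exp(log_dense), np.eye(4), "raw")


def corrupt(
    img: IntensityVolume,
    bias: IntensityVolume | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rician: bool = False,
) -> IntensityVolume:
    """out = img * bias + noise.  Bias first (coil sensitivity), then noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    data = img.data
    if bias is not None:
        if bias.shape != img.shape:
            raise ValueError(f"bias shape {bias.shape} != image shape {img.shape}")
        data = data * bias.data
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if rician:
            re = data + rng.standard_normal(data.shape) * noise_sd
            im = rng.standard_normal(data.shape) * noise_sd
            data = np.sqrt(re ** 2 + im ** 2)
        else:
            data = data + rng.standard_normal(data.shape) * noise_sd
    elif bias is None:
        data = data.copy()
    return IntensityVolume(data, img.affine.copy(), "raw")


def normalize_target(
    img: IntensityVolume, labels: LabelVolume, wm_code: int
) -> IntensityVolume:
    """Scale so the mean white-matter intensity is exactly 1.0 (target units)."""
    wm = labels.data == wm_code
    if not wm.any():
        raise ValueError(f"no voxels with white-matter code {wm_code}")
    m = img.data[wm].mean()
    if m == 0:
        raise ValueError("white-matter mean is zero; cannot normalize")
    return IntensityVolume(img.data / m, img.affine.copy(), "wm1")


def minmax01(img: IntensityVolume) -> IntensityVolume:
    """(img - min) / (max - min); the network's input normalization."""
    lo, hi = float(img.data.min()), float(img.data.max())
    if hi == lo:
        raise ValueError("constant image: min-max normalization is undefined")
    return IntensityVolume((img.data - lo) / (hi - lo), img.affine.copy(), "minmax01")
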