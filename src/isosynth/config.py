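"""Domain-randomization configuration: every sampling range of the generator.

All ranges are (low, high) pairs drawn uniformly, once per training sample,
so the network sees a fresh contrast / orientation / resolution / noise
condition at every iteration.  Units are stated per field; intensities are in
the normalized units of the generator (per-label means live in [0, 1] before
bias and noise).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class GeneratorConfig:
    # --- GMM contrast randomization (normalized intensity units) ---
    mean_range: tuple[float, float] = (0.0, 1.0)   # per-label mean  ~ U
    sd_range: tuple[float, float] = (0.0, 0.1)     # per-label sd    ~ U

    # --- bias field ---
    bias_log_amplitude: tuple[float, float] = (0.0, 0.4)  # sd of log-field ~ U
    bias_grid: int = 4                              # control grid nodes per axis

    # --- additive noise (after synthesis, normalized units) ---
    noise_sd_range: tuple[float, float] = (0.0, 0.08)
    rician: bool = False                            # Gaussian by default

    # --- acquisition geometry ---
    spacing_range: tuple[float, float] = (1.0, 9.0)  # slice spacing, mm
    thickness_range: tuple[float, float] | None = None  # None -> U(min(1,spacing), spacing)
    slice_profile: str = "gaussian"                 # or "boxcar"

    # --- linear geometric augmentation ---
    rot_range: float = 15.0        # degrees, per axis
    scale_range: float = 0.15      # scales ~ U(1-s, 1+s)
    shear_range: float = 0.012     # unitless
    trans_range: float = 5.0       # mm

    # --- diffeomorphic augmentation (stationary velocity field) ---
    svf_amplitude: float = 3.0     # max velocity sd, voxels (amp per sample ~ U(0, this))
    svf_spacing: int = 10          # control-grid spacing, voxels
    svf_steps: int = 7             # scaling-and-squaring steps

    # --- lesion simulation ---
    lesion_prob: float = 0.5
    lesion_code: int = 99

    # --- reference (target) rendering ---
    reference_noise_sd: float = 0.02  # texture sd of the clean target, wm-relative units

    def __post_init__(self):
        for name in ("mean_range", "sd_range", "bias_log_amplitude",
                     "noise_sd_range", "spacing_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: high < low ({lo}, {hi})")
        if self.spacing_range[0] <= 0:
            raise ValueError("slice spacing must be positive")
        if not 0 <= self.lesion_prob <= 1:
            raise ValueError("lesion_prob must be a probability")
        if self.scale_range >= 1:
            raise ValueError("scale_range >= 1 would allow non-positive scales")
        if self.slice_profile not in ("gaussian", "boxcar"):
            raise ValueError(f"unknown slice profile {self.slice_profile!r}")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def identity_limit(cls) -> "GeneratorConfig":
        """Degenerate configuration: no randomness anywhere.

        Zero GMM variances, no bias, no noise, isotropic acquisition with a
        vanishing slice profile, no geometric augmentation, no lesions.  The
        generator then reduces to the per-label mean image.
        """
        return cls(
            sd_range=(0.0, 0.0),
            bias_log_amplitude=(0.0, 0.0),
            noise_sd_range=(0.0, 0.0),
            spacing_range=(1.0, 1.0),
            thickness_range=(0.0, 0.0),
            rot_range=0.0, scale_range=0.0, shear_range=0.0, trans_range=0.0,
            svf_amplitude=0.0,
            lesion_prob=0.0,
            reference_noise_sd=0.0,
        )
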