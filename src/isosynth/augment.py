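"""Random spatial augmentation: affine transforms and diffeomorphic warps.

Affines act on world coordinates (mm).  Nonlinear deformations are modeled as
stationary velocity fields (SVFs) drawn i.i.d. Gaussian on a coarse control
grid, linearly upsampled, and exponentiated by scaling-and-squaring — the
standard construction guaranteeing (up to discretization) an invertible,
smooth warp.  Both are applied to a volume in a single resampling pass so
labels are interpolated only once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "AffineTransform",
    "VelocityField",
    "DeformationField",
    "sample_affine",
    "sample_velocity_field",
    "integrate_svf",
    "warp",
    "jacobian_determinant",
]


@dataclass
class AffineTransform:
    """4x4 homogeneous matrix in world mm coordinates (pull-back convention)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1)):
            raise ValueError("last row must be (0, 0, 0, 1)")
        if np.linalg.det(self.matrix[:3, :3]) <= 0:
            raise ValueError("linear part must have positive determinant")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


@dataclass
class VelocityField:
    """Stationary velocities (mm) on a coarse control grid.

    ``values`` has shape (3, gx, gy, gz); ``spacing`` is the control-grid
    spacing in voxels of the target grid, which doubles as the smoothing
    scale of the resulting dense field.
    """

    values: np.ndarray
    spacing: float
    amplitude: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[0] != 3:
            raise ValueError("velocity values must have shape (3, gx, gy, gz)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocities must be finite")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def negated(self) -> "VelocityField":
        return VelocityField(-self.values, self.spacing, self.amplitude)


@dataclass
class DeformationField:
    """Dense displacement (mm ≡ voxels on a 1-mm grid), shape (3, nx, ny, nz)."""

    displacement: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nx, ny, nz)")


def sample_affine(
    rot_range: float = 15.0,
    scale_range: float = 0.15,
    shear_range: float = 0.012,
    trans_range: float = 5.0,
    seed: int = 0,
) -> AffineTransform:
    """Draw a random affine: per-axis rotation (deg), scale, shear, translation (mm).

    Composition is T @ R @ (Shear @ Scale) with R built from intrinsic xyz
    Euler angles and Shear unit upper-triangular, so the draw can be exactly
    recovered by QR decomposition (used in tests).
    """
    for name, v in (("rot", rot_range), ("scale", scale_range),
                    ("shear", shear_range), ("trans", trans_range)):
        if v < 0:
            raise ValueError(f"{name}_range must be non-negative")
    if scale_range >= 1:
        raise ValueError("scale_range >= 1 would allow non-positive scales")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-rot_range, rot_range, 3)
    scales = rng.uniform(1 - scale_range, 1 + scale_range, 3)
    shears = rng.uniform(-shear_range, shear_range, 3)  # (xy, xz, yz)
    trans = rng.uniform(-trans_range, trans_range, 3)

    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = shears
    L = R @ Sh @ np.diag(scales)
    M = np.eye(4)
    M[:3, :3] = L
    M[:3, 3] = trans
    return AffineTransform(M)


def decompose_affine(t: AffineTransform) -> dict[str, np.ndarray]:
    """Invert sample_affine's composition: recover angles/scales/shears/translation."""
    L = t.matrix[:3, :3]
    Q, U = np.linalg.qr(L)
    sign = np.sign(np.diag(U))
    Q, U = Q * sign, U * sign[:, None]
    scales = np.diag(U).copy()
    Sh = U / scales  # unit upper triangular
    angles = Rotation.from_matrix(Q).as_euler("xyz", degrees=True)
    return {
        "angles": angles,
        "scales": scales,
        "shears": np.array([Sh[0, 1], Sh[0, 2], Sh[1, 2]]),
        "translation": t.matrix[:3, 3].copy(),
    }


def sample_velocity_field(
    shape: tuple[int, int, int],
    amplitude: float = 3.0,
    spacing: int = 10,
    seed: int = 0,
) -> VelocityField:
    """Gaussian i.i.d. velocities on a coarse grid covering ``shape``.

    The per-sample amplitude is drawn U(0, amplitude) — some samples are
    nearly undeformed, mirroring the variety the randomized generator
    wants — and the field is rescaled so its maximum velocity magnitude
    equals that draw: ``amplitude`` bounds the size of the deformation in
    voxels, keeping the integrated warp comfortably diffeomorphic.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0, amplitude)
    grid = tuple(int(np.ceil((n - 1) / spacing)) + 1 for n in shape)
    values = rng.standard_normal((3, *grid))
    maxmag = np.sqrt((values ** 2).sum(axis=0)).max()
    values *= amp / max(maxmag, 1e-12)
    return VelocityField(values, float(spacing), amplitude)


def _dense_velocity(v: VelocityField, shape: tuple[int, int, int]) -> np.ndarray:
    """Linearly upsample the control grid onto the full voxel grid."""
    dense = np.empty((3, *shape))
    coords = np.meshgrid(
        *[np.arange(n) / v.spacing for n in shape], indexing="ij"
    )
    coords = np.stack(coords)
    for c in range(3):
        dense[c] = ndimage.map_coordinates(v.values[c], coords, order=1, mode="nearest")
    return dense


def _compose_displacement(d_outer: np.ndarray, d_inner: np.ndarray,
                          order: int = 3) -> np.ndarray:
    """Displacement of phi_outer ∘ phi_inner where phi(x) = x + d(x).

    Cubic interpolation by default: the squaring steps compound any
    interpolation error, and linear sampling leaves the integrated warp
    measurably inverse-inconsistent at the default amplitude.
    """
    shape = d_inner.shape[1:]
    base = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
    coords = base + d_inner
    warped = np.empty_like(d_outer)
    for c in range(3):
        warped[c] = ndimage.map_coordinates(d_outer[c], coords, order=order, mode="nearest")
    return d_inner + warped


def integrate_svf(
    v: VelocityField, shape: tuple[int, int, int], n_steps: int = 7
) -> DeformationField:
    """Exponentiate a stationary velocity field by scaling and squaring.

    The dense velocity is divided by 2**n_steps and the resulting small
    displacement is self-composed n_steps times: phi = exp(v).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    d = _dense_velocity(v, shape) / (2.0 ** n_steps)
    for _ in range(n_steps):
        d = _compose_displacement(d, d)
    return DeformationField(d)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """det of the Jacobian of phi(x) = x + d(x), central differences."""
    d = field.displacement
    J = np.empty((3, 3, *d.shape[1:]))
    for c in range(3):
        grads = np.gradient(d[c], axis=(0, 1, 2))
        for ax in range(3):
            J[c, ax] = grads[ax]
        J[c, c] += 1.0
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return det


def warp(
    volume: LabelVolume | IntensityVolume,
    affine: AffineTransform | None = None,
    field: DeformationField | None = None,
    interp: str | None = None,
):
    """Resample a volume through affine ∘ diffeomorphic in one pass.

    The sampling position for output voxel x is  A(x + d(x))  expressed in
    voxel coordinates (world = voxel on the generator's 1-mm RAS grid up to
    the volume affine, through which world-space affines are mapped).
    Out-of-field voxels are filled with the background code (labels) or 0.
    """
    is_labels = isinstance(volume, LabelVolume)
    if interp is None:
        interp = "nearest" if is_labels else "linear"
    if is_labels and interp != "nearest":
        raise ValueError("label volumes must use nearest-neighbor interpolation")
    if interp not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    order = 0 if interp == "nearest" else 1
    shape = volume.shape

    coords = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
    if field is not None:
        coords = coords + field.displacement
    if affine is not None:
        vox2world = volume.affine
        world2vox = np.linalg.inv(vox2world)
        M = world2vox @ affine.matrix @ vox2world
        flat = coords.reshape(3, -1)
        coords = (M[:3, :3] @ flat + M[:3, 3:4]).reshape(coords.shape)

    data = ndimage.map_coordinates(
        volume.data.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )
    if is_labels:
        out = np.rint(data).astype(volume.data.dtype)
        return LabelVolume(out, volume.affine.copy(), dict(volume.label_table))
    return IntensityVolume(data, volume.affine.copy(), volume.units)
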