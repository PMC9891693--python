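"""Out-of-the-box inference: any-resolution, any-contrast volume in,
1-mm isotropic synthetic T1-weighted volume out.

The only preprocessing is the one the network was trained to expect:
reorient to RAS, trilinear resample to 1 mm isotropic, zero-pad each axis up
to the next multiple of 32 (five resolution levels halve the grid four
times), and min-max normalize to [0, 1].  No skull stripping, registration
or bias-field correction.  Everything needed to invert the padding is
recorded in ``PreprocMeta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nibabel.processing import resample_to_output

from .nn import NetworkState, forward
from .volumes import IntensityVolume

__all__ = ["PreprocMeta", "preprocess", "unpad", "synthesize_t1"]

PAD_MULTIPLE = 32


@dataclass
class PreprocMeta:
    original_shape: tuple[int, int, int]
    original_affine: np.ndarray
    resampled_shape: tuple[int, int, int]
    resampled_affine: np.ndarray
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]
    vmin: float
    vmax: float


def _pad_amounts(n: int, multiple: int = PAD_MULTIPLE) -> tuple[int, int]:
    """Symmetric split of the padding up to the next multiple.

    'Closest multiple' is resolved as round-UP: rounding down would crop
    anatomy, and a no-op when already a multiple.
    """
    target = int(np.ceil(n / multiple)) * multiple
    extra = target - n
    return extra // 2, extra - extra // 2


def preprocess(vol: IntensityVolume) -> tuple[IntensityVolume, PreprocMeta]:
    """RAS reorientation, 1-mm resampling, pad-to-32, min-max normalization."""
    if vol.data.ndim != 3:
        raise ValueError("inference expects a 3D single-channel volume")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img = nib.as_closest_canonical(img)
    if np.allclose(np.array(img.header.get_zooms()[:3]), 1.0, atol=1e-6) and \
            np.allclose(img.affine[:3, :3], np.diag([1.0, 1.0, 1.0]), atol=1e-6):
        res = img  # already conformed: resampling would be the identity
    else:
        res = resample_to_output(img, voxel_sizes=(1.0, 1.0, 1.0), order=1, cval=0.0)
    data = np.asanyarray(res.dataobj).astype(np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        raise ValueError("constant image: cannot min-max normalize")

    pads = [_pad_amounts(n) for n in data.shape]
    padded = np.pad(data, pads, constant_values=vmin)
    norm = (padded - vmin) / (vmax - vmin)
    # world position of the new voxel origin moves back by the leading pads
    pad_affine = res.affine.copy()
    pad_affine[:3, 3] -= pad_affine[:3, :3] @ np.array([p[0] for p in pads], dtype=float)
    meta = PreprocMeta(
        original_shape=tuple(vol.data.shape),
        original_affine=np.asarray(vol.affine, dtype=float),
        resampled_shape=tuple(data.shape),
        resampled_affine=np.asarray(res.affine, dtype=float),
        pad_before=tuple(p[0] for p in pads),
        pad_after=tuple(p[1] for p in pads),
        vmin=vmin, vmax=vmax,
    )
    return IntensityVolume(norm, pad_affine, "minmax01"), meta


def unpad(data: np.ndarray, meta: PreprocMeta) -> np.ndarray:
    sl = tuple(
        slice(b, n + b) for b, n in zip(meta.pad_before, meta.resampled_shape)
    )
    return data[sl]


def synthesize_t1(vol: IntensityVolume, state: NetworkState,
                  rescale: float | None = None) -> IntensityVolume:
    """Run the full pipeline: preprocess, predict, unpad.

    The output covers the input field of view on a 1-mm isotropic RAS grid.
    Intensities are left in model units ([0, 1]-trained scale) unless
    ``rescale`` multiplies them by a user factor.
    """
    pre, meta = preprocess(vol)
    yhat = forward(state, pre)[0].astype(np.float64)
    out = unpad(yhat, meta)
    if rescale is not None:
        out = out * rescale
    return IntensityVolume(out, meta.resampled_affine, "raw")
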