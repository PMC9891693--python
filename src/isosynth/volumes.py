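"""Core in-memory containers: integer label maps and scalar intensity volumes.

Both carry a 4x4 voxel-to-world affine (mm, RAS+ convention as in NIfTI-1).
Label maps additionally carry a label table mapping each integer code to an
anatomical role; code 0 is reserved for background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: valid roles for label codes
ROLES = ("background", "cerebral", "extracerebral", "lesion")


@dataclass
class LabelEntry:
    role: str
    name: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown label role {self.role!r}; expected one of {ROLES}")


@dataclass
class LabelVolume:
    """Integer-coded 3D anatomy map on a voxel grid.

    Parameters
    ----------
    data : ndarray of non-negative integers, shape (nx, ny, nz)
    affine : (4, 4) voxel-to-world map in mm
    label_table : mapping code -> LabelEntry; must cover every code in ``data``
        and contain exactly one background code (0).
    """

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, LabelEntry] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label data must be an integer array")
        if self.data.min() < 0:
            raise ValueError("label codes must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.validate()

    def validate(self):
        present = set(int(c) for c in np.unique(self.data))
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"codes {sorted(missing)} present in data but absent from label_table")
        backgrounds = [c for c, e in self.label_table.items() if e.role == "background"]
        if len(backgrounds) != 1 or backgrounds[0] != 0:
            raise ValueError("label_table must contain exactly one background code, 0")
        lesions = {c for c, e in self.label_table.items() if e.role == "lesion"}
        anat = {c for c, e in self.label_table.items() if e.role in ("cerebral", "extracerebral")}
        if lesions & anat:
            raise ValueError("lesion codes must be disjoint from anatomy codes")

    def codes(self, role: str | None = None) -> list[int]:
        """Sorted codes, optionally filtered by role."""
        if role is None:
            return sorted(self.label_table)
        return sorted(c for c, e in self.label_table.items() if e.role == role)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy(), dict(self.label_table))


@dataclass
class IntensityVolume:
    """Scalar 3D image on a voxel grid.

    ``units`` tags the intensity scale:

    - ``raw``      arbitrary units straight out of the generator;
    - ``minmax01`` min-max normalized to [0, 1] (network input scale);
    - ``wm1``      white-matter mean matched to 1.0 (regression target scale).
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("intensity data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity data must be finite")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.units not in ("raw", "minmax01", "wm1"):
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.units == "minmax01" and (self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9):
            raise ValueError("minmax01 volume has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.data.copy(), self.affine.copy(), self.units)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_labels(labels: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI plus a ``.labels.json`` sidecar table."""
    path = Path(path)
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine)
    nib.save(img, path)
    sidecar = _sidecar_path(path)
    table = {str(c): {"role": e.role, "name": e.name} for c, e in labels.label_table.items()}
    sidecar.write_text(json.dumps(table, indent=1))


def load_labels(path: str | Path, label_table: Mapping[int, LabelEntry] | None = None) -> LabelVolume:
    """Read a NIfTI label volume; the table comes from the sidecar unless given."""
    path = Path(path)
    img = nib.load(path)
    data = np.rint(np.asanyarray(img.dataobj)).astype(np.int32)
    if label_table is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            label_table = {int(c): LabelEntry(v["role"], v.get("name", "")) for c, v in raw.items()}
        else:
            # fall back: everything nonzero is a cerebral ROI
            label_table = {0: LabelEntry("background")}
            for c in np.unique(data):
                if c != 0:
                    label_table[int(c)] = LabelEntry("cerebral")
    return LabelVolume(data, img.affine, dict(label_table))


def save_intensity(vol: IntensityVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), Path(path))


def load_intensity(path: str | Path, units: str = "raw") -> IntensityVolume:
    img = nib.load(Path(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return IntensityVolume(data, img.affine, units)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")
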