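"""Procedural brain-like label phantoms and synthetic lesion insertion.

The phantom is a stand-in for manually labeled training anatomy: nested
smooth-boundary regions (background shell, extracerebral layers, cortical
ribbon, white matter, deep-gray blobs, a central ventricle cavity) built from
perturbed concentric ellipsoids.  It is not anatomically faithful — it exists
so that the whole generative pipeline can be exercised without any data
download — but it reproduces the structural features the generator relies on:
a designated white-matter class, a cerebral/extracerebral split and smooth
curved interfaces between classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelEntry, LabelVolume

__all__ = [
    "PhantomGeometry",
    "LesionBank",
    "generate_phantom_labels",
    "synthetic_lesion_mask",
    "insert_lesion",
]


@dataclass
class PhantomGeometry:
    """Normalized radii (fractions of the ellipsoid radius) of the shells.

    The cohort generator modulates these with age to emulate atrophy.
    """

    brain_radius: float = 0.75     # cortex outer surface
    cortex_inner: float = 0.62     # cortex/white-matter interface
    ventricle_radius: float = 0.18
    semiaxis_frac: float = 0.42    # ellipsoid semi-axes as fraction of shape
    wiggle_amplitude: float = 0.06  # smooth boundary perturbation of rho
    deep_blob_frac: float = 0.08   # deep-gray blob radius as fraction of min(shape)


@dataclass
class LesionBank:
    """A list of binary lesion masks used to paint synthetic pathology."""

    masks: list[np.ndarray] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        for i, m in enumerate(self.masks):
            m = np.asarray(m)
            if m.dtype != bool:
                m = m.astype(bool)
                self.masks[i] = m
            if m.ndim != 3 or not m.any():
                raise ValueError(f"lesion mask {i} must be a nonempty binary 3D array")
        if len(self.provenance) != len(self.masks):
            self.provenance = ["synthetic"] * len(self.masks)

    def __len__(self) -> int:
        return len(self.masks)


def _rho(shape: tuple[int, int, int], geom: PhantomGeometry, rng: np.random.Generator) -> np.ndarray:
    """Perturbed normalized ellipsoidal radius field (0 at center)."""
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    rho2 = np.zeros(shape)
    for g, n in zip(grids, shape):
        a = geom.semiaxis_frac * n
        rho2 += ((g - (n - 1) / 2.0) / a) ** 2
    rho = np.sqrt(rho2)
    if geom.wiggle_amplitude > 0:
        noise = rng.standard_normal(shape)
        sigma = max(2.0, min(shape) / 12.0)
        smooth = ndimage.gaussian_filter(noise, sigma)
        smooth /= max(smooth.std(), 1e-12)
        # self-similar perturbation: scales with rho so the small central
        # structures keep their volume while outer boundaries wiggle freely
        rho = rho + geom.wiggle_amplitude * smooth * np.minimum(rho, 1.0)
    return rho


def generate_phantom_labels(
    shape: tuple[int, int, int],
    n_cerebral: int = 6,
    n_extracerebral: int = 3,
    seed: int = 0,
    geometry: PhantomGeometry | None = None,
) -> LabelVolume:
    """Build a deterministic brain-like label phantom.

    Codes are assigned contiguously: 0 background, 1..n_extracerebral the
    extracerebral shells (outermost first), then the cerebral classes:
    cortex, white matter, ventricle (if n_cerebral >= 3) and deep-gray blobs.
    The white-matter class is always present and named ``white-matter`` in
    the label table.

    Every requested class is guaranteed to occupy at least 0.1% of voxels;
    the call fails if the geometry cannot satisfy that.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError("phantom shape must be 3D with every dimension >= 32")
    if n_cerebral < 2:
        raise ValueError("need at least cortex + white matter (n_cerebral >= 2)")
    if n_extracerebral < 0:
        raise ValueError("n_extracerebral must be >= 0")
    geom = geometry or PhantomGeometry()
    rng = np.random.default_rng(seed)
    rho = _rho(shape, geom, rng)

    ne = n_extracerebral
    cortex_code = ne + 1
    wm_code = ne + 2
    vent_code = ne + 3 if n_cerebral >= 3 else None
    n_blobs = max(0, n_cerebral - 3)

    data = np.zeros(shape, dtype=np.int32)
    # extracerebral shells between brain_radius and 1
    if ne > 0:
        edges = np.linspace(1.0, geom.brain_radius, ne + 1)
        for i in range(ne):
            data[(rho < edges[i]) & (rho >= edges[i + 1])] = 1 + i
    # cortex ribbon and white matter core
    data[(rho < geom.brain_radius) & (rho >= geom.cortex_inner)] = cortex_code
    data[rho < geom.cortex_inner] = wm_code
    if vent_code is not None:
        data[rho < geom.ventricle_radius] = vent_code

    # deep-gray blobs: spheres planted strictly inside the white matter
    blob_r = max(3.0, geom.deep_blob_frac * min(shape))
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    min_frac = 1e-3
    for b in range(n_blobs):
        code = ne + 4 + b if vent_code is not None else ne + 3 + b
        placed = False
        for _attempt in range(50):
            # random direction + radius inside the WM annulus
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            rad = rng.uniform(geom.ventricle_radius + 0.12, geom.cortex_inner - 0.14)
            center = np.array([(n - 1) / 2.0 for n in shape]) + \
                u * rad * geom.semiaxis_frac * np.array(shape)
            d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            sphere = d2 <= blob_r ** 2
            paint = sphere & (data == wm_code)
            if paint.sum() >= min_frac * data.size:
                data[paint] = code
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place deep-gray blob {b} with >=0.1% volume")

    table = {0: LabelEntry("background", "background")}
    for i in range(ne):
        table[1 + i] = LabelEntry("extracerebral", f"extracerebral-{i}")
    table[cortex_code] = LabelEntry("cerebral", "cortex")
    table[wm_code] = LabelEntry("cerebral", "white-matter")
    if vent_code is not None:
        table[vent_code] = LabelEntry("cerebral", "ventricle")
    first_blob = vent_code + 1 if vent_code is not None else wm_code + 1
    for b in range(n_blobs):
        table[first_blob + b] = LabelEntry("cerebral", f"deep-gray-{b}")

    labels = LabelVolume(data, np.eye(4), table)
    counts = np.bincount(data.ravel(), minlength=max(table) + 1)
    for code in table:
        if counts[code] < min_frac * data.size:
            raise ValueError(
                f"class {code} ({table[code].name}) occupies {counts[code]} voxels "
                f"(< 0.1% of {data.size}); shape too small for requested classes"
            )
    return labels


def wm_code_of(labels: LabelVolume) -> int:
    """The designated white-matter code (by name, else the largest cerebral class)."""
    for c, e in labels.label_table.items():
        if e.name == "white-matter":
            return c
    cerebral = labels.codes("cerebral")
    if not cerebral:
        raise ValueError("label volume has no cerebral classes")
    counts = np.bincount(labels.data.ravel(), minlength=max(cerebral) + 1)
    return int(max(cerebral, key=lambda c: counts[c]))


def synthetic_lesion_mask(
    shape: tuple[int, int, int],
    n_blobs: int,
    radius_range: tuple[float, float],
    seed: int = 0,
) -> np.ndarray:
    """Union of random spherical blobs; populates a LesionBank without real data."""
    shape = tuple(int(s) for s in shape)
    if n_blobs < 1:
        raise ValueError("a lesion mask needs at least one blob (empty masks are invalid)")
    lo, hi = radius_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid radius range")
    if 2 * hi + 1 > min(shape):
        raise ValueError("radii do not fit in shape")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        r = rng.uniform(lo, hi)
        margin = r + 0.5
        center = [rng.uniform(margin, n - 1 - margin) if n - 1 > 2 * margin else (n - 1) / 2
                  for n in shape]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        mask |= d2 <= max(r, 0.0) ** 2 + 1e-9  # r=0 rounds to the center voxel
    if not mask.any():
        # r=0 with non-integer center can miss the lattice; paint nearest voxel
        mask[tuple(int(round(c)) for c in center)] = True
    return mask


_ORIENTATIONS = [(p, f) for p in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
                 for f in range(8)]


def insert_lesion(
    labels: LabelVolume,
    bank: LesionBank,
    lesion_prob: float,
    lesion_code: int,
    seed: int = 0,
    max_attempts: int = 10,
) -> LabelVolume:
    """Randomly place one lesion from the bank inside cerebral tissue.

    With probability ``lesion_prob`` a mask is drawn from the bank, rigidly
    placed (random axis permutation/flip + integer translation) and painted
    as ``lesion_code`` — but only over voxels currently labeled cerebral, so
    lesions never leak into skull or background.  Placements with empty
    cerebral overlap are resampled up to ``max_attempts`` times, then skipped.
    """
    if not 0 <= lesion_prob <= 1:
        raise ValueError("lesion_prob must be in [0, 1]")
    if lesion_code in labels.label_table and labels.label_table[lesion_code].role != "lesion":
        raise ValueError(f"code {lesion_code} already used for anatomy")
    if lesion_prob > 0 and len(bank) == 0:
        raise ValueError("lesion bank is empty")
    rng = np.random.default_rng(seed)
    if lesion_prob == 0 or rng.random() >= lesion_prob:
        return labels

    cerebral = np.isin(labels.data, labels.codes("cerebral"))
    out = labels.data.copy()
    shape = np.array(labels.shape)
    for _ in range(max_attempts):
        mask = bank.masks[rng.integers(len(bank))]
        perm, flips = _ORIENTATIONS[rng.integers(len(_ORIENTATIONS))]
        m = np.transpose(mask, perm)
        for ax in range(3):
            if flips >> ax & 1:
                m = np.flip(m, axis=ax)
        msh = np.array(m.shape)
        lo = np.array([rng.integers(-s // 2, n - s // 2 + 1) for s, n in zip(msh, shape)])
        # overlap of the translated mask with the volume
        src_lo = np.maximum(0, -lo)
        dst_lo = np.maximum(0, lo)
        extent = np.minimum(msh - src_lo, shape - dst_lo)
        if np.any(extent <= 0):
            continue
        src = tuple(slice(a, a + e) for a, e in zip(src_lo, extent))
        dst = tuple(slice(a, a + e) for a, e in zip(dst_lo, extent))
        hit = np.zeros(labels.shape, dtype=bool)
        hit[dst] = m[src]
        paint = hit & cerebral
        if paint.any():
            out[paint] = lesion_code
            table = dict(labels.label_table)
            table[lesion_code] = LabelEntry("lesion", "lesion")
            return LabelVolume(out, labels.affine.copy(), table)
    return labels
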