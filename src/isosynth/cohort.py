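"""Phantom cohorts: label maps + reference intensities + demographics.

The cohort generator is the end-to-end test harness: it produces the whole
chain of inputs the rest of the package consumes — per-subject label
phantoms whose ventricles grow and cortex thins with age (an adjustable
"atrophy rule"), MPRAGE-like reference renderings, and matched volume
tables with controllable measurement noise for exercising the evaluation
statistics against known ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import canonical_reference
from .phantom import PhantomGeometry, generate_phantom_labels
from .volumes import IntensityVolume, LabelVolume, save_intensity, save_labels

__all__ = ["Subject", "PhantomCohort", "make_cohort", "make_eval_tables", "write_cohort"]


@dataclass
class Subject:
    subject: str
    age: float
    sex: str
    icv: float            # mm^3, cerebral voxel count on the 1-mm grid
    labels: LabelVolume
    reference: IntensityVolume


@dataclass
class PhantomCohort:
    subjects: list[Subject]
    seed: int
    shape: tuple[int, int, int]
    atrophy_rule: str
    age_range: tuple[float, float] = (20.0, 90.0)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            h = hashlib.sha256(s.labels.data.tobytes()).hexdigest()[:16]
            rows.append({
                "subject": s.subject, "age": s.age, "sex": s.sex,
                "icv": s.icv, "labels_sha": h,
            })
        return pd.DataFrame(rows)

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            self.manifest().to_csv(index=False).encode()
        ).hexdigest()

    def volume_table(self) -> pd.DataFrame:
        """Exact per-ROI volumes (mm^3) straight from the label counts."""
        rows = []
        for s in self.subjects:
            counts = np.bincount(s.labels.data.ravel(),
                                 minlength=max(s.labels.label_table) + 1)
            row = {"subject": s.subject, "scan": 0, "age": s.age,
                   "sex": s.sex, "icv": s.icv}
            for code, entry in sorted(s.labels.label_table.items()):
                if entry.role == "cerebral":
                    row[entry.name] = float(counts[code])
            rows.append(row)
        return pd.DataFrame(rows)


def _geometry_for(age: float, age_range: tuple[float, float],
                  rule: str) -> PhantomGeometry:
    if rule == "none":
        return PhantomGeometry()
    if rule == "linear":
        lo, hi = age_range
        t = np.clip((age - lo) / max(hi - lo, 1e-9), 0.0, 1.0)
        # ventricles enlarge, cortex thins with age
        return PhantomGeometry(
            ventricle_radius=0.16 + 0.10 * t,
            cortex_inner=0.60 + 0.05 * t,
        )
    raise ValueError(f"unknown atrophy rule {rule!r}")


def make_cohort(
    n_subjects: int,
    shape: tuple[int, int, int] = (48, 48, 48),
    age_range: tuple[float, float] = (20.0, 90.0),
    atrophy_rule: str = "none",
    seed: int = 0,
    n_cerebral: int = 6,
    n_extracerebral: int = 3,
) -> PhantomCohort:
    """Deterministic cohort of label phantoms with demographics.

    Ages are uniform over ``age_range``; the atrophy rule maps age to the
    phantom geometry (``'none'`` keeps every subject's geometry identical up
    to the random boundary wiggle; ``'linear'`` plants monotone ventricle
    growth and cortical thinning).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        age = float(rng.uniform(*age_range))
        sex = "F" if rng.random() < 0.5 else "M"
        sub_seed = int(rng.integers(2 ** 31 - 1))
        geom = _geometry_for(age, age_range, atrophy_rule)
        labels = generate_phantom_labels(shape, n_cerebral, n_extracerebral,
                                         seed=sub_seed, geometry=geom)
        reference = canonical_reference(labels, noise_sd=0.02, seed=sub_seed)
        cerebral = np.isin(labels.data, labels.codes("cerebral"))
        icv = float(cerebral.sum())  # 1-mm voxels -> mm^3
        subjects.append(Subject(f"sub-{i:03d}", age, sex, icv, labels, reference))
    return PhantomCohort(subjects, seed, tuple(shape), atrophy_rule, age_range)


def make_eval_tables(
    cohort: PhantomCohort,
    volumetric_noise_sd: float = 0.0,
    seed: int = 0,
    bias: float = 1.0,
    n_scans: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(truth, pred) volume tables with known measurement error.

    Truth holds the exact phantom ROI volumes; pred = bias * truth + noise,
    independently per scan — ``n_scans`` replicate rows per subject emulate
    repeated clinical acquisitions of one session.
    """
    if volumetric_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    base = cohort.volume_table()
    rois = [c for c in base.columns if c not in ("subject", "scan", "age", "sex", "icv")]
    rng = np.random.default_rng(seed)
    truth_rows, pred_rows = [], []
    for _, row in base.iterrows():
        for scan in range(n_scans):
            t = row.copy()
            t["scan"] = scan
            truth_rows.append(t)
            p = t.copy()
            for roi in rois:
                p[roi] = bias * t[roi] + rng.normal(0, volumetric_noise_sd)
            pred_rows.append(p)
    return (pd.DataFrame(truth_rows).reset_index(drop=True),
            pd.DataFrame(pred_rows).reset_index(drop=True))


def write_cohort(cohort: PhantomCohort, outdir) -> None:
    """NIfTI volumes + TSV manifest, reproducible from (code, seed) alone."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        save_labels(s.labels, out / f"{s.subject}_labels.nii.gz")
        save_intensity(s.reference, out / f"{s.subject}_reference.nii.gz")
    m = cohort.manifest()
    m["cohort_hash"] = cohort.manifest_hash()
    m.to_csv(out / "manifest.tsv", sep="\t", index=False)
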