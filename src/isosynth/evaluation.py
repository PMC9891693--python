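"""Evaluation statistics for ROI volumetry on heterogeneous clinical cohorts.

Reusable pieces of a volumetric validation study:

- per-ROI Pearson agreement between predicted and reference volumes, at the
  scan level or aggregated per subject by the median across scans;
- covariate correction of volumes by intracranial volume (ICV) and sex;
- robust age-trajectory regression — a Laplace likelihood whose location and
  scale are each cubic B-splines with six knots over the age range (the
  heavy Laplace tails resist the outliers that clinical segmentations
  produce, where a Gaussian fit would be dragged);
- nonparametric two-group comparison: medians, Wilcoxon rank-sum p, AUROC.

A volume table is a plain pandas DataFrame with metadata columns
(``subject``, ``scan``, ``age``, ``sex``, ``icv``, optionally ``spacing``)
and one column per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "META_COLS",
    "roi_columns",
    "correlate_volumes",
    "residualize",
    "LaplaceSplineFit",
    "fit_laplace_spline",
    "group_compare",
    "normality_check",
    "plot_trajectory",
]

META_COLS = ("subject", "scan", "age", "sex", "icv", "spacing")


def roi_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def correlate_volumes(
    pred: pd.DataFrame, truth: pd.DataFrame, level: str = "scan"
) -> pd.DataFrame:
    """Per-ROI Pearson r (and two-sided p) between matched volume tables.

    ``level='scan'`` matches rows on (subject, scan); ``level='subject'``
    first aggregates each subject's scans by the median, making the result
    invariant to how many scans a subject contributed.
    """
    rois = [c for c in roi_columns(pred) if c in roi_columns(truth)]
    if not rois:
        raise ValueError("no shared ROI columns between tables")
    if level == "scan":
        keys = ["subject", "scan"] if "scan" in pred.columns else ["subject"]
        merged = pred.merge(truth, on=keys, suffixes=("_pred", "_true"))
    elif level == "subject":
        p = pred.groupby("subject")[rois].median()
        t = truth.groupby("subject")[rois].median()
        merged = p.join(t, lsuffix="_pred", rsuffix="_true", how="inner")
    else:
        raise ValueError("level must be 'scan' or 'subject'")
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} matched rows; need >= 3")
    rows = []
    for roi in rois:
        r, p_val = stats.pearsonr(merged[f"{roi}_pred"], merged[f"{roi}_true"])
        rows.append({"roi": roi, "r": r, "p": p_val, "n": len(merged)})
    return pd.DataFrame(rows).set_index("roi")


def residualize(volumes, icv, sex) -> np.ndarray:
    """Remove the least-squares ICV and sex effects; keep the grand mean.

    ``sex`` may be any two-level coding (strings or 0/1)."""
    y = np.asarray(volumes, dtype=float)
    icv = np.asarray(icv, dtype=float)
    sex = np.asarray(sex)
    if np.unique(icv).size < 2:
        raise ValueError("ICV is constant; cannot correct for it")
    levels = np.unique(sex)
    if levels.size < 2:
        raise ValueError("sex is constant; cannot correct for it")
    if levels.size > 2:
        raise ValueError("sex must be a two-level covariate")
    sex01 = (sex == levels[1]).astype(float)
    X = np.column_stack([np.ones_like(y), icv, sex01])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta + y.mean()


# ---------------------------------------------------------------------------
# Laplace-spline age regression
# ---------------------------------------------------------------------------

_SMOOTH_EPS = 1e-6  # Huber-type smoothing of |r| in the Laplace likelihood


def _spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix with clamped boundary knots."""
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    x = np.clip(x, knots[0], knots[-1] - 1e-12)
    return BSpline.design_matrix(x, t, k=3).toarray()


@dataclass
class LaplaceSplineFit:
    """Fitted location/scale curves m(age), s(age) of a Laplace model.

    y | age  ~  Laplace(m(age), s(age)),  both curves cubic B-splines over
    ``knots``; ``s`` is kept positive through a log link.
    """

    knots: np.ndarray
    beta: np.ndarray    # location coefficients
    gamma: np.ndarray   # log-scale coefficients
    nll: float
    cov_beta: np.ndarray

    def predict(self, age) -> np.ndarray:
        """Fitted median (= location) curve."""
        return _spline_basis(np.atleast_1d(np.asarray(age, float)), self.knots) @ self.beta

    def scale(self, age) -> np.ndarray:
        return np.exp(
            _spline_basis(np.atleast_1d(np.asarray(age, float)), self.knots) @ self.gamma
        )

    def band(self, age, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the median curve (delta method on
        the asymptotic covariance of the location coefficients)."""
        B = _spline_basis(np.atleast_1d(np.asarray(age, float)), self.knots)
        m = B @ self.beta
        se = np.sqrt(np.maximum((B @ self.cov_beta * B).sum(axis=1), 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return m - z * se, m + z * se


def fit_laplace_spline(
    age, y, n_knots: int = 6, n_restarts: int = 3, seed: int = 0
) -> LaplaceSplineFit:
    """Maximum-likelihood Laplace regression with spline location and scale.

    Maximizes  sum_i [ -|y_i - m(age_i)| / s(age_i) - log 2 s(age_i) ]  over
    the spline coefficients of m and log s.  The non-smooth |.| is replaced
    by sqrt(r^2 + eps^2), eps = 1e-6, and the smoothed objective is solved
    with multi-start L-BFGS (restarts perturb the initial coefficients).
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.shape != y.shape or age.ndim != 1:
        raise ValueError("age and y must be matching 1D arrays")
    n = len(y)
    if n < 10 * n_knots:
        raise ValueError(f"need >= {10 * n_knots} observations for {n_knots} knots")
    knots = np.quantile(age, np.linspace(0, 1, n_knots))
    if np.any(np.diff(knots) <= 0):
        raise ValueError("ages too concentrated: duplicate knots")
    B = _spline_basis(age, knots)
    p = B.shape[1]

    def objective(params):
        beta, gamma = params[:p], params[p:]
        m = B @ beta
        logs = np.clip(B @ gamma, -20.0, 20.0)
        s = np.exp(logs)
        r = y - m
        a = np.sqrt(r ** 2 + _SMOOTH_EPS ** 2)
        nll = np.sum(a / s + logs) + n * np.log(2.0)
        dm = -(r / a) / s
        dlogs = 1.0 - a / s
        grad = np.concatenate([B.T @ dm, B.T @ dlogs])
        return nll, grad

    beta0, *_ = np.linalg.lstsq(B, y, rcond=None)
    r0 = y - B @ beta0
    gamma0 = np.zeros(p)
    gamma0[:] = np.log(max(np.mean(np.abs(r0)), 1e-12))
    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_restarts)):
        x0 = np.concatenate([beta0, gamma0])
        if k > 0:
            x0 = x0 + rng.normal(0, 0.05 * max(1.0, np.abs(x0).max()), x0.size)
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Laplace-spline fit did not converge")
    beta, gamma = best.x[:p], best.x[p:]
    # asymptotic covariance of the location block: Fisher info for a Laplace
    # location parameter is 1/s^2 per observation
    s = np.exp(np.clip(B @ gamma, -20.0, 20.0))
    info = B.T @ (B / (s ** 2)[:, None])
    cov_beta = np.linalg.pinv(info)
    return LaplaceSplineFit(knots, beta, gamma, float(best.fun), cov_beta)


# ---------------------------------------------------------------------------
# Nonparametric group comparison
# ---------------------------------------------------------------------------

def group_compare(a, b) -> dict[str, float]:
    """Medians, two-sided Wilcoxon rank-sum p, and AUROC.

    AUROC = P(random a > random b) + 0.5 P(tie), computed from the rank-sum
    statistic with average ranks, hence exact under ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra = ranks[: len(a)].sum()
    auroc = (ra - len(a) * (len(a) + 1) / 2) / (len(a) * len(b))
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "wilcoxon_p": float(p),
        "auroc": float(auroc),
    }


def normality_check(values) -> float:
    """Shapiro-Wilk p-value (delegated; 3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    return float(stats.shapiro(values).pvalue)


def plot_trajectory(age, y, fit: LaplaceSplineFit, path, roi: str = "") -> None:
    """Scatter + fitted median curve + 95% band (age-trajectory figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    age = np.asarray(age, float)
    grid = np.linspace(age.min(), age.max(), 200)
    lo, hi = fit.band(grid)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(age, y, s=6, alpha=0.35, color="steelblue", linewidths=0)
    ax.plot(grid, fit.predict(grid), color="crimson", lw=2, label="median")
    ax.fill_between(grid, lo, hi, color="crimson", alpha=0.25, label="95% CI")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{roi} volume (mm$^3$)" if roi else "volume (mm$^3$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
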