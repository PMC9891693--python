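"""Evaluation statistics: correlations, covariate correction, Laplace splines,
nonparametric group comparison."""

import numpy as np
import pandas as pd
import pytest

from isosynth.evaluation import (
    correlate_volumes,
    fit_laplace_spline,
    group_compare,
    normality_check,
    residualize,
)


def _table(vals: dict, subject=None, scan=None):
    n = len(next(iter(vals.values())))
    return pd.DataFrame({
        "subject": subject if subject is not None else [f"s{i}" for i in range(n)],
        "scan": scan if scan is not None else [0] * n,
        "age": np.linspace(20, 80, n),
        "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "icv": np.full(n, 1.4e6),
        **vals,
    })


class TestCorrelateVolumes:
    def test_identical_tables_give_r_one(self, rng):
        t = _table({"hippocampus": rng.random(10) * 1000})
        res = correlate_volumes(t, t)
        assert res.loc["hippocampus", "r"] == pytest.approx(1.0)

    def test_negated_gives_minus_one(self, rng):
        v = rng.random(10) * 1000
        res = correlate_volumes(_table({"roi": -v + 5000}), _table({"roi": v}))
        assert res.loc["roi", "r"] == pytest.approx(-1.0)

    def test_fisher_z_calibration(self):
        # true r = 0.8, n = 435: estimates land in the Fisher-z band ~95% of runs
        hits = 0
        reps = 200
        for s in range(reps):
            r = np.random.default_rng(s)
            x = r.standard_normal(435)
            y = 0.8 * x + np.sqrt(1 - 0.64) * r.standard_normal(435)
            res = correlate_volumes(_table({"roi": x}), _table({"roi": y}))
            hits += 0.76 <= res.loc["roi", "r"] <= 0.84
        assert hits / reps >= 0.90

    def test_subject_level_median_invariance(self, rng):
        v = rng.random(8) * 1000
        w = v + rng.normal(0, 10, 8)
        subj = [f"s{i}" for i in range(8)]
        pred = _table({"roi": v}, subject=subj)
        truth = _table({"roi": w}, subject=subj)
        base = correlate_volumes(pred, truth, level="subject")
        # duplicate one subject's scan three times: median aggregation ignores it
        dup = pd.concat([pred, pred.iloc[[0]], pred.iloc[[0]], pred.iloc[[0]]],
                        ignore_index=True)
        dup.loc[8:, "scan"] = [1, 2, 3]
        dup_res = correlate_volumes(dup, truth, level="subject")
        assert dup_res.loc["roi", "r"] == pytest.approx(base.loc["roi", "r"])

    def test_too_few_pairs_rejected(self, rng):
        t = _table({"roi": rng.random(2)})
        with pytest.raises(ValueError):
            correlate_volumes(t, t)


class TestResidualize:
    def test_independent_volumes_unchanged(self, rng):
        v = rng.normal(1000, 50, 200)
        icv = rng.normal(1.4e6, 1e5, 200)
        sex = rng.integers(0, 2, 200)
        out = residualize(v, icv, sex)
        assert np.allclose(out, v, atol=3 * 50 / np.sqrt(200) * 5)
        assert abs(np.corrcoef(out, icv)[0, 1]) < 0.05

    def test_orthogonality_exact(self, rng):
        v = rng.normal(0, 1, 100) + 0.5 * rng.normal(0, 1, 100)
        icv = rng.normal(1.4e6, 1e5, 100)
        sex = rng.integers(0, 2, 100)
        out = residualize(v + icv * 1e-4, icv, sex)
        centered = out - out.mean()
        assert abs(np.dot(centered, icv - icv.mean()) /
                   (np.linalg.norm(centered) * np.linalg.norm(icv - icv.mean()))) < 1e-10

    def test_planted_slope_removed(self, rng):
        icv = rng.normal(1.4e6, 1e5, 500)
        sex = rng.integers(0, 2, 500)
        v = 2e-3 * icv + 100 * sex + rng.normal(0, 1, 500)
        out = residualize(v, icv, sex)
        slope = np.polyfit(icv, out, 1)[0]
        assert abs(slope) < 1e-8

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            residualize(rng.random(10), np.ones(10), rng.integers(0, 2, 10))


class TestLaplaceSpline:
    def test_constant_model_recovery(self):
        r = np.random.default_rng(0)
        age = r.uniform(20, 90, 2000)
        c, b = 5000.0, 300.0
        y = c + b * (r.exponential(1, 2000) - r.exponential(1, 2000))  # Laplace(c, b)
        fit = fit_laplace_spline(age, y)
        grid = np.linspace(25, 85, 50)
        m = fit.predict(grid)
        assert np.abs(m - c).max() < abs(c) * 0.02 + 0.02 * b
        s = fit.scale(grid)
        assert np.abs(s - b).max() < 0.25 * b

    def test_more_robust_than_gaussian(self):
        # symmetric 10% contamination: Laplace location drifts less than LS
        from isosynth.evaluation import _spline_basis

        r = np.random.default_rng(1)
        n = 1500
        age = r.uniform(20, 90, n)
        true = 1000 + 5 * age
        y = true + r.laplace(0, 50, n)
        out = r.random(n) < 0.10
        y[out] += r.choice([-1, 1], out.sum()) * r.uniform(500, 2000, out.sum())
        fit = fit_laplace_spline(age, y)
        B = _spline_basis(age, fit.knots)
        beta_ls, *_ = np.linalg.lstsq(B, y, rcond=None)
        grid = np.linspace(25, 85, 50)
        Bg = _spline_basis(grid, fit.knots)
        err_laplace = np.abs(fit.predict(grid) - (1000 + 5 * grid)).mean()
        err_gauss = np.abs(Bg @ beta_ls - (1000 + 5 * grid)).mean()
        assert err_laplace < err_gauss

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_laplace_spline(rng.uniform(20, 90, 30), rng.random(30))


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["auroc"] == pytest.approx(0.5)

    def test_fully_separated(self):
        res = group_compare([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert res["auroc"] == 1.0

    def test_tied_example_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = group_compare(a, b)
        wins = sum(x > y for x in a for y in b)
        ties = sum(x == y for x in a for y in b)
        assert res["auroc"] == pytest.approx((wins + 0.5 * ties) / 9)
        assert res["median_a"] == 2.0 and res["median_b"] == 3.0

    def test_wilcoxon_detects_shift(self, rng):
        a = rng.normal(1.5, 1.0, 60)
        b = rng.normal(0.0, 1.0, 60)
        assert group_compare(a, b)["wilcoxon_p"] < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestNormalityCheck:
    def test_gaussian_rejection_rate_calibrated(self):
        n_reject = sum(
            normality_check(np.random.default_rng(s).standard_normal(500)) < 0.05
            for s in range(1000)
        )
        assert 0.03 <= n_reject / 1000 <= 0.07

    def test_lognormal_detected(self):
        rejected = sum(
            normality_check(np.exp(np.random.default_rng(s).standard_normal(500))) < 0.05
            for s in range(100)
        )
        assert rejected > 99 * 0.99

    def test_n_bounds(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
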