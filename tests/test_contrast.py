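"""GMM contrast synthesis, bias field, noise and normalizations."""

import numpy as np
import pytest

from isosynth.contrast import (
    BiasFieldParams,
    GMMParams,
    corrupt,
    minmax01,
    normalize_target,
    sample_bias_field,
    sample_gmm,
    synthesize,
)
from isosynth.phantom import wm_code_of
from isosynth.volumes import IntensityVolume, LabelEntry, LabelVolume


def _single_label_volume(shape=(32, 32, 32), code=1):
    data = np.full(shape, code, dtype=np.int32)
    data[0, 0, 0] = 0  # keep a background voxel so the table is valid
    table = {0: LabelEntry("background"), code: LabelEntry("cerebral", "white-matter")}
    return LabelVolume(data, np.eye(4), table)


class TestSampleGMM:
    def test_zero_sd_range(self):
        g = sample_gmm({1, 2, 3}, (0, 1), (0, 0), seed=0)
        assert all(s == 0 for s in g.sds.values())

    def test_sampler_mean_is_calibrated(self):
        # Monte-Carlo check: U(0,1) means average to 0.5
        draws = [sample_gmm({1}, (0, 1), (0, 0.1), seed=s).means[1] for s in range(10_000)]
        assert 0.49 <= np.mean(draws) <= 0.51

    def test_seed_determinism(self):
        a = sample_gmm({1, 2}, (0, 1), (0, 0.1), seed=3)
        b = sample_gmm({1, 2}, (0, 1), (0, 0.1), seed=3)
        assert a.means == b.means and a.sds == b.sds

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            sample_gmm(set(), (0, 1), (0, 0.1), seed=0)


class TestSynthesize:
    def test_zero_variance_gives_piecewise_constant(self, phantom32):
        codes = phantom32.codes()
        g = GMMParams({c: 0.1 * c for c in codes}, {c: 0.0 for c in codes})
        img = synthesize(phantom32, g, seed=0)
        for c in codes:
            region = img.data[phantom32.data == c]
            assert np.allclose(region, 0.1 * c)

    def test_sample_mean_within_clt_bound(self):
        lab = _single_label_volume()
        g = GMMParams({0: 0.6, 1: 0.6}, {0: 0.1, 1: 0.1})
        img = synthesize(lab, g, seed=1)
        n = img.data.size
        assert abs(img.data.mean() - 0.6) < 3 * 0.1 / np.sqrt(n)

    def test_per_label_mean_recovery(self, phantom32):
        # conditional-mean property: empirical per-class means match mu_k
        codes = phantom32.codes()
        g = sample_gmm(codes, (0, 1), (0.05, 0.05), seed=2)
        img = synthesize(phantom32, g, seed=3)
        for c in codes:
            vals = img.data[phantom32.data == c]
            assert abs(vals.mean() - g.means[c]) < 3 * g.sds[c] / np.sqrt(len(vals))

    def test_missing_params_rejected(self, phantom32):
        g = GMMParams({0: 0.5}, {0: 0.1})
        with pytest.raises(ValueError):
            synthesize(phantom32, g, seed=0)

    def test_seed_contract(self, phantom32):
        g = sample_gmm(phantom32.codes(), seed=0)
        a = synthesize(phantom32, g, seed=5)
        b = synthesize(phantom32, g, seed=5)
        c = synthesize(phantom32, g, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_contrast_inversions_covered(self):
        # over many draws, white matter is brighter than gray about half the time
        wins = sum(
            sample_gmm({1, 2}, seed=s).means[1] > sample_gmm({1, 2}, seed=s).means[2]
            for s in range(2000)
        )
        assert 0.45 < wins / 2000 < 0.55


class TestBiasField:
    def test_zero_amplitude_is_unity(self):
        f = sample_bias_field((16, 16, 16), BiasFieldParams(4, 0.0), seed=0)
        assert np.allclose(f.data, 1.0)

    def test_strictly_positive(self):
        for s in range(5):
            f = sample_bias_field((16, 16, 16), BiasFieldParams(4, 0.5), seed=s)
            assert f.data.min() > 0

    def test_smoother_than_iid_noise(self, rng):
        # discrete Laplacian energy well below an i.i.d. field of equal variance
        def lap_energy(x):
            e = 0.0
            for ax in range(3):
                e += (np.diff(x, axis=ax) ** 2).sum()
            return e

        ratios = []
        for s in range(20):
            f = np.log(sample_bias_field((24, 24, 24), BiasFieldParams(4, 0.4), seed=s).data)
            iid = rng.normal(0, f.std() + 1e-12, f.shape)
            ratios.append(lap_energy(f) / lap_energy(iid))
        assert np.mean(ratios) < 0.2

    def test_grid_guard(self):
        with pytest.raises(ValueError):
            BiasFieldParams(1, 0.1)


class TestCorrupt:
    def test_identity_when_clean(self):
        img = IntensityVolume(np.random.default_rng(0).random((8, 8, 8)), np.eye(4))
        out = corrupt(img, None, 0.0)
        assert np.array_equal(out.data, img.data)

    def test_mean_matches_bias_product(self):
        img = IntensityVolume(np.full((64, 64, 64), 0.5), np.eye(4))
        bias = IntensityVolume(np.full((64, 64, 64), 1.2), np.eye(4))
        out = corrupt(img, bias, noise_sd=0.05, seed=1)
        assert abs(out.data.mean() - 0.6) < 3 * 0.05 / np.sqrt(out.data.size)

    def test_noise_variance_calibrated(self):
        img = IntensityVolume(np.zeros((64, 64, 64)), np.eye(4))
        out = corrupt(img, None, noise_sd=0.1, seed=2)
        assert abs(out.data.var() - 0.01) / 0.01 < 0.05

    def test_shape_mismatch_rejected(self):
        img = IntensityVolume(np.zeros((8, 8, 8)), np.eye(4))
        bias = IntensityVolume(np.ones((9, 8, 8)), np.eye(4))
        with pytest.raises(ValueError):
            corrupt(img, bias, 0.0)


class TestNormalizations:
    def test_wm_normalization_halves(self, phantom32):
        wm = wm_code_of(phantom32)
        img = IntensityVolume(np.full(phantom32.shape, 2.0), np.eye(4))
        out = normalize_target(img, phantom32, wm)
        assert np.allclose(out.data, 1.0)
        assert out.units == "wm1"

    def test_wm_mean_exactly_one(self, phantom32):
        wm = wm_code_of(phantom32)
        img = IntensityVolume(np.random.default_rng(1).random(phantom32.shape) + 0.5,
                              np.eye(4))
        out = normalize_target(img, phantom32, wm)
        assert abs(out.data[phantom32.data == wm].mean() - 1.0) < 1e-9

    def test_idempotent(self, phantom32):
        wm = wm_code_of(phantom32)
        img = IntensityVolume(np.random.default_rng(2).random(phantom32.shape) + 0.5,
                              np.eye(4))
        once = normalize_target(img, phantom32, wm)
        twice = normalize_target(once, phantom32, wm)
        assert np.allclose(once.data, twice.data)

    def test_missing_wm_rejected(self, phantom32):
        img = IntensityVolume(np.ones(phantom32.shape), np.eye(4))
        with pytest.raises(ValueError):
            normalize_target(img, phantom32, wm_code=77)

    def test_minmax_binary(self):
        img = IntensityVolume(np.array([[[2.0, 4.0]]] * 2), np.eye(4))
        out = minmax01(img)
        assert set(np.unique(out.data)) == {0.0, 1.0}

    def test_minmax_affine_invariance(self, rng):
        img = IntensityVolume(rng.random((8, 8, 8)), np.eye(4))
        for a, b in [(2.0, 1.0), (0.5, -3.0), (10.0, 100.0)]:
            scaled = IntensityVolume(a * img.data + b, np.eye(4))
            assert np.allclose(minmax01(scaled).data, minmax01(img).data)

    def test_minmax_constant_rejected(self):
        img = IntensityVolume(np.full((4, 4, 4), 3.0), np.eye(4))
        with pytest.raises(ValueError):
            minmax01(img)
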