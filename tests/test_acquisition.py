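"""Acquisition geometry: slice-profile partial volume, subsampling, pipeline."""

import numpy as np
import pytest
from scipy.integrate import quad

from isosynth.acquisition import (
    AcquisitionParams,
    degrade,
    make_training_sample,
    sample_acquisition,
)
from isosynth.config import GeneratorConfig
from isosynth.volumes import IntensityVolume

FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def oracle_degrade_1d(values: np.ndarray, spacing: float, thickness: float) -> np.ndarray:
    """Independent brute-force reference for the 1-D degradation.

    Treats the samples as a continuous piecewise-constant signal (voxel i
    spans [i-1/2, i+1/2]), averages it under a Gaussian slice profile at
    each slice center by adaptive numerical quadrature, and linearly
    interpolates back to the integer grid.
    """
    n = len(values)
    sd = thickness * FWHM_TO_SD
    centers = np.arange(0.0, n - 1 + 1e-9, spacing)
    slice_vals = []
    for c in centers:
        num = den = 0.0
        for i in range(n):
            g = lambda t: np.exp(-((t - c) ** 2) / (2 * sd ** 2))  # noqa: E731
            q, _ = quad(g, i - 0.5, i + 0.5, epsabs=1e-14, epsrel=1e-12)
            num += values[i] * q
            den += q
        slice_vals.append(num / den)
    return np.interp(np.arange(n, dtype=float), centers, np.array(slice_vals))


class TestSampleAcquisition:
    def test_isotropic_limit(self):
        acq = sample_acquisition((1.0, 1.0), seed=0)
        assert acq.spacing == 1.0 and acq.thickness == 1.0

    def test_axis_frequencies_uniform(self):
        counts = {"sagittal": 0, "coronal": 0, "axial": 0}
        n = 3000
        for s in range(n):
            counts[sample_acquisition((1, 9), seed=s).axis] += 1
        for v in counts.values():
            assert 0.30 <= v / n <= 0.37

    def test_thickness_rule(self):
        for s in range(200):
            acq = sample_acquisition((2.0, 8.0), seed=s)
            assert 1.0 <= acq.thickness <= acq.spacing + 1e-12

    def test_seed_determinism(self):
        a = sample_acquisition((1, 9), seed=4)
        b = sample_acquisition((1, 9), seed=4)
        assert (a.axis, a.spacing, a.thickness) == (b.axis, b.spacing, b.thickness)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            sample_acquisition((0.0, 5.0), seed=0)


class TestDegrade:
    def test_identity_limit(self, rng):
        img = IntensityVolume(rng.random((16, 16, 16)), np.eye(4))
        out = degrade(img, AcquisitionParams("axial", 1.0, 0.0))
        assert np.allclose(out.data, img.data, atol=1e-12)

    def test_constant_preserved(self):
        img = IntensityVolume(np.full((24, 24, 24), 0.7), np.eye(4))
        out = degrade(img, AcquisitionParams("coronal", 5.0, 4.0))
        assert np.allclose(out.data, 0.7)

    @pytest.mark.parametrize("thickness,spacing", [(3.0, 3.0), (5.0, 5.0), (3.0, 6.0)])
    def test_step_edge_matches_oracle(self, thickness, spacing):
        n = 48
        values = np.where(np.arange(n) < n // 2, 0.2, 0.9)
        vol = IntensityVolume(np.tile(values[:, None, None], (1, 4, 4)), np.eye(4))
        out = degrade(vol, AcquisitionParams("sagittal", spacing, thickness))
        expected = oracle_degrade_1d(values, spacing, thickness)
        assert np.abs(out.data[:, 0, 0] - expected).max() < 1e-6

    def test_in_plane_untouched(self, rng):
        img = IntensityVolume(rng.random((24, 24, 24)), np.eye(4))
        out = degrade(img, AcquisitionParams("axial", 6.0, 4.0))
        # degrading along z must not mix xy content: a z-constant image is fixed
        flat = IntensityVolume(np.tile(img.data[:, :, :1], (1, 1, 24)), np.eye(4))
        out_flat = degrade(flat, AcquisitionParams("axial", 6.0, 4.0))
        assert np.allclose(out_flat.data, flat.data, atol=1e-9)

    def test_linearity(self, rng):
        u = IntensityVolume(rng.random((24, 24, 24)), np.eye(4))
        v = IntensityVolume(rng.random((24, 24, 24)), np.eye(4))
        acq = AcquisitionParams("coronal", 4.0, 3.0)
        lhs = degrade(IntensityVolume(2 * u.data + 3 * v.data, np.eye(4)), acq)
        rhs = 2 * degrade(u, acq).data + 3 * degrade(v, acq).data
        assert np.abs(lhs.data - rhs).max() < 1e-6

    def test_nyquist_attenuation(self, rng):
        # energy above the sampling Nyquist drops relative to the input
        img = IntensityVolume(rng.standard_normal((64, 16, 16)), np.eye(4))
        spacing = 4.0
        out = degrade(img, AcquisitionParams("sagittal", spacing, spacing))
        freqs = np.fft.rfftfreq(64, d=1.0)
        band = freqs > 1.0 / (2 * spacing)
        p_in = (np.abs(np.fft.rfft(img.data, axis=0)) ** 2)[band].mean()
        p_out = (np.abs(np.fft.rfft(out.data, axis=0)) ** 2)[band].mean()
        assert p_out < 0.2 * p_in

    def test_spacing_exceeding_fov_rejected(self):
        img = IntensityVolume(np.zeros((16, 16, 16)), np.eye(4))
        with pytest.raises(ValueError):
            degrade(img, AcquisitionParams("axial", 40.0, 3.0))

    def test_anisotropic_input_rejected(self):
        aff = np.diag([2.0, 1.0, 1.0, 1.0])
        img = IntensityVolume(np.zeros((16, 16, 16)), aff)
        with pytest.raises(ValueError):
            degrade(img, AcquisitionParams("axial", 3.0, 3.0))


class TestMakeTrainingSample:
    def test_identity_limit_alignment(self, phantom32, identity_config):
        s = make_training_sample(phantom32, identity_config, seed=5)
        # piecewise-constant input perfectly aligned with the label target
        assert np.array_equal(s.labels.data, phantom32.data)
        n_classes = len(np.unique(phantom32.data))
        assert len(np.unique(s.x.data)) == n_classes
        for c in np.unique(phantom32.data):
            assert np.unique(s.x.data[s.labels.data == c]).size == 1

    def test_seed_reproducibility(self, phantom32, default_config, lesion_bank):
        a = make_training_sample(phantom32, default_config, seed=9, lesion_bank=lesion_bank)
        b = make_training_sample(phantom32, default_config, seed=9, lesion_bank=lesion_bank)
        assert np.array_equal(a.x.data, b.x.data)
        assert np.array_equal(a.y.data, b.y.data)
        assert np.array_equal(a.labels.data, b.labels.data)

    def test_shapes_and_grids_match(self, phantom32, default_config):
        s = make_training_sample(phantom32, default_config, seed=1)
        assert s.x.shape == s.y.shape == s.labels.shape == phantom32.shape
        assert np.allclose(s.x.affine, s.y.affine)
        assert np.allclose(s.x.affine, phantom32.affine)

    def test_target_is_wm_normalized(self, phantom32, default_config):
        s = make_training_sample(phantom32, default_config, seed=2)
        wm = s.labels.data == s.meta["wm_code"]
        assert abs(s.y.data[wm].mean() - 1.0) < 1e-9

    def test_lesion_free_target(self, phantom32, default_config, lesion_bank):
        cfg = GeneratorConfig(lesion_prob=1.0)
        s = make_training_sample(phantom32, cfg, seed=3, lesion_bank=lesion_bank)
        # segmentation/regression targets never contain the lesion code
        assert cfg.lesion_code not in np.unique(s.labels.data)
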