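"""CVR estimation: smoothing, absolute GLM, global regressor, relative maps."""

import numpy as np
import pytest

import chp_elastic as ce
from chp_elastic.errors import InvalidArgumentError

from oracles import gaussian_kernel_1d, ols_normal_equations


def make_series(data, tr=2000.0, te=(25.0,), mask=None):
    acq = ce.AcquisitionParams(tr=tr, te_list=te, flip_angle=80.0, n_volumes=data.shape[-1])
    if mask is None:
        mask = np.ones(data.shape[:3], bool)
    return ce.BoldSeries(data, acq, mask)


class TestSmoothing:
    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(0)
        b = make_series(rng.random((6, 6, 4, 5)) + 1)
        out = ce.smooth_gaussian(b, 0.0)
        assert np.array_equal(out.data, b.data)

    def test_delta_function_matches_separable_kernel(self):
        """A point source smoothed at FWHM 4 mm / 2 mm voxels is the discrete
        Gaussian kernel (unit sum), cross-checked against an outer-product oracle."""
        acq = ce.AcquisitionParams(tr=2000.0, te_list=(25.0,), flip_angle=80.0,
                                   n_volumes=2, voxel_size=(2.0, 2.0, 2.0))
        data = np.zeros((15, 15, 15, 2))
        data[7, 7, 7, :] = 1.0
        b = ce.BoldSeries(data, acq, np.ones((15, 15, 15), bool))
        out = ce.smooth_gaussian(b, 4.0).data[..., 0]
        sigma = 4.0 / np.sqrt(8 * np.log(2)) / 2.0  # in voxels
        k = gaussian_kernel_1d(sigma)
        r = (len(k) - 1) // 2
        expected = np.einsum("i,j,k->ijk", k, k, k)
        sub = out[7 - r : 7 + r + 1, 7 - r : 7 + r + 1, 7 - r : 7 + r + 1]
        assert out.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(sub, expected, atol=1e-12)

    def test_constant_volume_preserved(self):
        b = make_series(np.full((8, 8, 4, 3), 7.0))
        out = ce.smooth_gaussian(b, 4.0)
        assert np.allclose(out.data, 7.0, atol=1e-10)

    def test_anisotropic_voxels_honored(self):
        """A thinner voxel axis gets proportionally more smoothing in voxel units."""
        data = np.zeros((21, 21, 21, 2))
        data[10, 10, 10, :] = 1.0
        acq = ce.AcquisitionParams(tr=2000.0, te_list=(25.0,), flip_angle=80.0,
                                   n_volumes=2, voxel_size=(1.0, 2.0, 4.0))
        b = ce.BoldSeries(data, acq, np.ones((21, 21, 21), bool))
        out = ce.smooth_gaussian(b, 6.0).data[..., 0]
        spread_x = (out[:, 10, 10] > 1e-6).sum()
        spread_z = (out[10, 10, :] > 1e-6).sum()
        assert spread_x > spread_z


class TestAbsoluteCvr:
    def test_constant_voxel_zero_cvr(self):
        data = np.full((4, 4, 2, 50), 100.0)
        b = make_series(data)
        et = ce.EtCO2Series(b.volume_times, 40 + 8 * (np.arange(50) % 10 > 4))
        cmap = ce.fit_cvr_glm(b, et)
        assert np.allclose(cmap.values, 0.0, atol=1e-10)

    def test_recovers_constructed_cvr_exactly(self):
        """Noiseless multiplicative response: recovered CVR equals truth to 1e-6."""
        n = 60
        et_values = 40 + 8 * (np.arange(n) % 20 >= 10)
        d = et_values - et_values.mean()
        cvr_true = 0.20
        data = np.empty((3, 3, 2, n))
        data[:] = 400.0 * (1 + cvr_true / 100.0 * d)
        b = make_series(data)
        cmap = ce.fit_cvr_glm(b, ce.EtCO2Series(b.volume_times, et_values))
        assert np.allclose(cmap.values, cvr_true, atol=1e-6)

    def test_centered_drift_absorbed(self):
        """Adding a mean-zero linear drift changes CVR by < 1e-8."""
        n = 60
        rng = np.random.default_rng(1)
        et_values = 40 + 8 * (np.arange(n) % 20 >= 10)
        base = 300 + 50 * rng.random((4, 4, 2, 1))
        data = base * (1 + 0.002 * (et_values - et_values.mean()))
        b = make_series(data)
        m1 = ce.fit_cvr_glm(b, ce.EtCO2Series(b.volume_times, et_values))
        t = np.arange(n) - (n - 1) / 2
        b2 = make_series(data + 0.5 * t)
        m2 = ce.fit_cvr_glm(b2, ce.EtCO2Series(b2.volume_times, et_values))
        assert np.abs(m1.values - m2.values).max() < 1e-8

    def test_matches_normal_equation_oracle(self, small_phantom):
        series, truth = small_phantom
        b = series[0]
        et = ce.EtCO2Series(truth.volume_times, truth.drive)
        cmap = ce.fit_cvr_glm(b, et)
        t = np.arange(b.acq.n_volumes, dtype=float)
        X = np.column_stack([np.ones_like(t), et.values, t])
        for idx in zip(*np.nonzero(b.brain_mask)):
            y = b.data[idx]
            beta = ols_normal_equations(X, y)
            expected = 100.0 * beta[1] / y.mean()
            assert cmap.values[idx] == pytest.approx(expected, rel=1e-8)

    def test_percent_scale_invariance(self, small_phantom):
        """CVR in percent units is invariant to a global intensity scale."""
        series, truth = small_phantom
        b = series[0]
        et = ce.EtCO2Series(truth.volume_times, truth.drive)
        m1 = ce.fit_cvr_glm(b, et)
        b2 = ce.BoldSeries(b.data * 3.7, b.acq, b.brain_mask)
        m2 = ce.fit_cvr_glm(b2, et)
        assert np.allclose(m1.values, m2.values, rtol=1e-10, atol=1e-12)

    def test_zero_variance_regressor_rejected(self):
        b = make_series(np.random.default_rng(0).random((3, 3, 2, 20)) + 1)
        with pytest.raises(InvalidArgumentError, match="zero variance"):
            ce.fit_cvr_glm(b, ce.EtCO2Series(b.volume_times, np.full(20, 40.0)))


class TestGlobalRegressor:
    @staticmethod
    def _sine_series(freq, n=200, tr=1500.0):
        t = np.arange(n) * tr / 1000.0
        wave = np.sin(2 * np.pi * freq * t)
        data = np.empty((3, 3, 2, n))
        data[:] = 500.0 + 10.0 * wave
        return make_series(data, tr=tr, te=(37.0,)), wave

    def test_stopband_attenuation(self):
        b, wave = self._sine_series(0.25)
        out = ce.global_regressor(b, cutoff=0.1164)
        # evaluate away from the zero-phase filter's edge transients
        assert np.ptp(out[30:-30]) < 0.1 * np.ptp(10 * wave)

    def test_passband_preserved(self):
        from scipy.signal import detrend

        b, wave = self._sine_series(0.02)
        out = ce.global_regressor(b, cutoff=0.1164)
        # the 0.02 Hz component should pass the filter essentially unchanged;
        # compare against the detrended input, away from edge transients
        reference = detrend(b.global_mean(), type="linear")
        assert np.ptp(out[30:-30]) == pytest.approx(np.ptp(reference[30:-30]), rel=0.05)

    def test_constant_input_zero(self):
        b = make_series(np.full((3, 3, 2, 50), 200.0), tr=1500.0, te=(37.0,))
        out = ce.global_regressor(b)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        b = make_series(np.full((3, 3, 2, 50), 200.0), tr=2000.0)
        with pytest.raises(InvalidArgumentError, match="Nyquist"):
            ce.global_regressor(b, cutoff=0.3)


class TestRelativeCvr:
    def test_homogeneous_response_all_ones(self):
        rng = np.random.default_rng(2)
        n = 120
        reg = np.sin(2 * np.pi * 0.02 * np.arange(n) * 1.5)
        data = 300.0 + 5.0 * reg + 0.1 * rng.standard_normal((5, 5, 3, n))
        b = make_series(data, tr=1500.0, te=(37.0,))
        m = ce.fit_relative_cvr(b, reg)
        assert m.units == "r.u."
        assert m.values[m.mask].mean() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(m.values[m.mask], 1.0, atol=0.05)

    def test_mask_mean_exactly_one(self, small_phantom):
        series, _ = small_phantom
        reg = ce.global_regressor(series[0], cutoff=0.1164)
        m = ce.fit_relative_cvr(series[0], reg)
        assert m.values[m.mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_negative_norm_flagged_not_raised(self):
        """If the whole-brain mean coefficient is negative, the unnormalized
        map is returned with a flag."""
        n = 80
        reg = np.sin(np.linspace(0, 12, n))
        data = np.empty((3, 3, 2, n))
        data[:] = 200.0 - 4.0 * reg  # uniformly anti-correlated brain
        b = make_series(data)
        m = ce.fit_relative_cvr(b, reg)
        assert m.metadata["normalized"] is False
        assert m.metadata["normalization_constant"] < 0
        assert np.all(m.values[m.mask] < 0)

    def test_motion_covariates_absorb_artifact(self):
        rng = np.random.default_rng(3)
        n = 100
        reg = np.sin(2 * np.pi * 0.03 * np.arange(n) * 1.5)
        spike = np.zeros(n)
        spike[40:60] = 5.0
        data = 300.0 + 4.0 * reg + 30.0 * spike + 0.1 * rng.standard_normal((4, 4, 2, n))
        b = make_series(data, tr=1500.0, te=(37.0,))
        with_mot = ce.fit_relative_cvr(b, reg, motion=spike[:, None])
        assert np.allclose(with_mot.values[with_mot.mask], 1.0, atol=0.05)
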