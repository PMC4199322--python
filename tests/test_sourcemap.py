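"""Beamformer algebra: covariance pooling, unit-gain LCMV, amplitude/Z maps."""

import numpy as np
import pytest

from hgmap import (Leadfield, SourceTFMap, TFCoefficients, TrialSet,
                   average_amplitude, broadband_covariance, lcmv_transfer,
                   map_coefficients, morlet_transform, zscore_baseline)
from hgmap.sourcemap import LCMVBeamformer

FS = 1200.0


def _ts(data):
    n = data.shape[-1]
    return TrialSet(data, FS, np.arange(n) / FS,
                    np.array(["left"] * data.shape[0]))


def _tf(coef, freqs=None, times=None):
    coef = np.asarray(coef)
    freqs = np.asarray(freqs if freqs is not None else np.arange(coef.shape[2]) + 70.0,
                       dtype=float)
    times = np.asarray(times if times is not None else np.arange(coef.shape[3]) * 0.01,
                       dtype=float)
    valid = np.ones((freqs.size, times.size), dtype=bool)
    return TFCoefficients(coef, freqs, times, valid, domain="source")


class TestCovariance:
    def test_white_noise_near_identity(self):
        rng = np.random.default_rng(0)
        ts = _ts(rng.standard_normal((1, 6, 1_000_000)))
        c = broadband_covariance(ts)
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 0.05
        np.testing.assert_allclose(np.diag(c), 1.0, atol=0.02)

    def test_constant_channels_zero(self):
        ts = _ts(np.ones((2, 4, 500)))
        np.testing.assert_allclose(broadband_covariance(ts), 0.0, atol=1e-15)

    def test_trial_order_free(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((5, 4, 400))
        c1 = broadband_covariance(_ts(data))
        c2 = broadband_covariance(_ts(data[::-1]))
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_flagged_trials_excluded(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 3, 300))
        data[2] *= 100.0
        ts = _ts(data)
        ts.artifact_flags[2] = True
        c = broadband_covariance(ts)
        assert np.abs(np.diag(c)).max() < 10.0

    def test_rank_deficient_warns(self):
        ts = _ts(np.random.default_rng(3).standard_normal((1, 50, 30)))
        with pytest.warns(UserWarning):
            broadband_covariance(ts)


class TestLCMV:
    def test_identity_covariance_closed_form(self, small_mesh_lf):
        _, lf = small_mesh_lf
        tm = lcmv_transfer(lf, np.eye(lf.n_channels), reg_lambda=0.0)
        expected = (lf.gain / (lf.gain**2).sum(axis=0)).T
        np.testing.assert_allclose(tm.T, expected, rtol=1e-10)

    def test_unit_gain_invariant(self, small_mesh_lf):
        _, lf = small_mesh_lf
        rng = np.random.default_rng(0)
        a = rng.standard_normal((lf.n_channels, 200))
        c = a @ a.T / 200
        tm = lcmv_transfer(lf, c, reg_lambda=0.05)
        gains = np.einsum("vc,cv->v", tm.T, lf.gain)
        np.testing.assert_allclose(gains, 1.0, atol=1e-6)

    def test_noiseless_source_localized(self, small_mesh_lf):
        """The source with maximum beamformer output variance is the true one."""
        _, lf = small_mesh_lf
        rng = np.random.default_rng(4)
        true_v = 17
        s = rng.standard_normal(2000)
        x = np.outer(lf.gain[:, true_v], s)
        c = x @ x.T / x.shape[1]
        tm = lcmv_transfer(lf, c, reg_lambda=0.001)
        var = np.einsum("vc,cd,vd->v", tm.T, c, tm.T)
        assert int(np.argmax(var)) == true_v

    def test_broken_covariance_raises(self, small_mesh_lf):
        _, lf = small_mesh_lf
        with pytest.raises(ValueError):
            lcmv_transfer(lf, -np.eye(lf.n_channels), reg_lambda=0.0)

    def test_estimator_wrapper(self, small_mesh_lf):
        _, lf = small_mesh_lf
        rng = np.random.default_rng(5)
        ts = _ts(rng.standard_normal((4, lf.n_channels, 500)))
        est = LCMVBeamformer(leadfield=lf, reg_lambda=0.05).fit(ts)
        assert est.transfer_.T.shape == (lf.n_sources, lf.n_channels)
        assert est.get_params()["reg_lambda"] == 0.05


class TestMapCoefficients:
    def test_identity_map(self):
        rng = np.random.default_rng(0)
        d = _tf(rng.standard_normal((2, 3, 2, 4)) + 1j * rng.standard_normal((2, 3, 2, 4)))
        j = map_coefficients(np.eye(3), d)
        np.testing.assert_allclose(j.coef, d.coef)
        assert j.domain == "source"

    def test_zero_coefficients(self):
        d = _tf(np.zeros((1, 3, 2, 4), dtype=complex))
        j = map_coefficients(np.random.default_rng(1).standard_normal((5, 3)), d)
        np.testing.assert_array_equal(j.coef, 0.0)

    def test_commutes_with_morlet(self):
        """T (morlet x) == morlet (T x): both operators are linear."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 4, 1200))
        t_mat = rng.standard_normal((5, 4))
        d = morlet_transform(x, [75.0, 80.0], fs=FS)
        left = map_coefficients(t_mat, d).coef
        right = morlet_transform(np.einsum("vc,ict->ivt", t_mat, x),
                                 [75.0, 80.0], fs=FS).coef
        np.testing.assert_allclose(left, right, rtol=1e-8, atol=1e-12)

    def test_dimension_mismatch(self):
        d = _tf(np.zeros((1, 3, 2, 4), dtype=complex))
        with pytest.raises(ValueError):
            map_coefficients(np.eye(4), d)


class TestAmplitude:
    def test_single_trial(self):
        rng = np.random.default_rng(0)
        coef = rng.standard_normal((1, 2, 2, 3)) + 1j * rng.standard_normal((1, 2, 2, 3))
        m = average_amplitude(_tf(coef))
        np.testing.assert_allclose(m.a, np.abs(coef[0]))

    def test_constant_magnitude_arithmetic(self):
        coef = np.full((3, 1, 1, 4), 2.0 + 0.0j)
        m = average_amplitude(_tf(coef), with_power=True)
        np.testing.assert_allclose(m.a, 6.0)
        np.testing.assert_allclose(m.p, 12.0)

    def test_duplication_doubles(self):
        rng = np.random.default_rng(1)
        coef = rng.standard_normal((2, 2, 1, 3)) + 1j * rng.standard_normal((2, 2, 1, 3))
        m1 = average_amplitude(_tf(coef), with_power=True)
        m2 = average_amplitude(_tf(np.concatenate([coef, coef])), with_power=True)
        np.testing.assert_allclose(m2.a, 2 * m1.a)
        np.testing.assert_allclose(m2.p, 2 * m1.p)

    def test_all_flagged_raises(self):
        coef = np.zeros((2, 1, 1, 3), dtype=complex)
        with pytest.raises(ValueError):
            average_amplitude(_tf(coef), artifact_flags=np.array([True, True]))


class TestZScore:
    def _map(self, a, times):
        a = np.asarray(a, dtype=float)
        return SourceTFMap(a=a, freqs_hz=np.array([80.0]),
                           time_s=np.asarray(times), n_trials=3,
                           valid=np.ones((1, len(times)), dtype=bool))

    def test_textbook_arithmetic(self):
        """Baseline {1,2,3}, signal 4 with sample SD gives Z = 2."""
        m = self._map([[[1.0, 2.0, 3.0, 4.0]]], [-0.75, -0.5, -0.25, 0.25])
        z = zscore_baseline(m).z
        assert z[0, 0, 3] == pytest.approx(2.0)

    def test_flat_postcue_is_zero(self):
        m = self._map([[[1.0, 2.0, 3.0, 2.0, 2.0]]], [-0.75, -0.5, -0.25, 0.25, 0.5])
        z = zscore_baseline(m).z
        np.testing.assert_allclose(z[0, 0, 3:], 0.0, atol=1e-12)

    def test_constant_map_invalid(self):
        m = self._map(np.ones((2, 1, 5)), [-0.75, -0.5, -0.25, 0.25, 0.5])
        out = zscore_baseline(m)
        assert not out.z_valid.any()
        assert np.isnan(out.z).all()

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 2, size=(3, 2, 8))
        times = np.linspace(-0.9, 0.8, 8)
        m1 = zscore_baseline(self._map(a, times))
        m2 = zscore_baseline(self._map(37.5 * a, times))
        np.testing.assert_allclose(m1.z, m2.z, rtol=1e-9)

    def test_baseline_must_be_valid(self):
        m = self._map([[[1.0, 2.0, 3.0, 4.0]]], [-0.75, -0.5, -0.25, 0.25])
        m.valid[0, 0] = False
        with pytest.raises(ValueError):
            zscore_baseline(m)
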