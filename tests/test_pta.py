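import numpy as np
import pytest

from pulsepop import pta


class TestDesign:
    def test_column_count_is_28(self):
        d = pta.build_design(np.ones((3, 7)), trial_len_ms=1200, resolution_ms=10)
        assert d.D.shape == (3 * 120, 28)

    def test_all_zero_pulses_give_zero_matrix(self):
        d = pta.build_design(np.zeros((5, 7)), resolution_ms=10)
        assert not np.any(d.D)

    def test_unit_pulse_support_is_250ms_after_onset(self):
        P = np.zeros((1, 7))
        P[0, 0] = 1.0
        d = pta.build_design(P, trial_len_ms=1200, resolution_ms=1)
        active = np.flatnonzero(np.any(d.D != 0, axis=1))
        assert active.min() == 0 and active.max() == 249
        # pulse 1 occupies the first four columns only
        assert not np.any(d.D[:, 4:])

    def test_basis_magnitude_scales_with_pulse_value(self):
        P1, P3 = np.zeros((1, 7)), np.zeros((1, 7))
        P1[0, 2], P3[0, 2] = 1.0, 3.0
        d1 = pta.build_design(P1, resolution_ms=10)
        d3 = pta.build_design(P3, resolution_ms=10)
        np.testing.assert_allclose(d3.D, 3.0 * d1.D)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            pta.build_design(np.ones((3, 6)))


class TestGcv:
    def _linear_data(self, seed, noise):
        rng = np.random.default_rng(seed)
        P = rng.normal(0, 2, (100, 7))
        d = pta.build_design(P, trial_len_ms=1200, resolution_ms=10)
        w = rng.normal(0, 1, 28)
        X = d.D @ w + noise * rng.standard_normal(d.D.shape[0])
        return d, X, w

    def test_noiseless_data_selects_small_lambda(self):
        d, X, w = self._linear_data(0, noise=0.0)
        lam, info = pta.gcv_select(d.D, X)
        assert lam <= info["grid"][1]  # selected at/near the grid minimum
        W = pta._ridge_solve(d.D, X[:, None], 0.0)
        ols = np.linalg.lstsq(d.D, X, rcond=None)[0]
        assert np.max(np.abs(W[:, 0] - ols)) < 1e-6

    def test_pure_noise_selects_large_lambda(self):
        rng = np.random.default_rng(1)
        P = rng.normal(0, 2, (100, 7))
        d = pta.build_design(P, trial_len_ms=1200, resolution_ms=10)
        X = rng.standard_normal(d.D.shape[0])
        lam, info = pta.gcv_select(d.D, X)
        assert lam >= info["grid"][-3]

    def test_single_value_grid_returned(self):
        d, X, _ = self._linear_data(2, noise=0.5)
        lam, _ = pta.gcv_select(d.D, X, grid=np.array([3.14]))
        assert lam == 3.14

    def test_selection_invariant_to_trial_permutation(self):
        rng = np.random.default_rng(3)
        P = rng.normal(0, 2, (60, 7))
        d = pta.build_design(P, resolution_ms=10)
        X = d.D @ rng.normal(0, 1, 28) + rng.standard_normal(d.D.shape[0])
        lam1, _ = pta.gcv_select(d.D, X)
        perm = rng.permutation(60)
        bins = d.bins_per_trial
        idx = (perm[:, None] * bins + np.arange(bins)).ravel()
        lam2, _ = pta.gcv_select(d.D[idx], X[idx])
        assert lam1 == lam2


class TestFitPta:
    def test_ridge_at_zero_matches_least_squares_oracle(self):
        rng = np.random.default_rng(4)
        P = rng.normal(0, 2, (80, 7))
        d = pta.build_design(P, resolution_ms=10)
        X = d.D @ rng.normal(0, 1, 28) + 0.1 * rng.standard_normal(d.D.shape[0])
        W = pta._ridge_solve(d.D, X[:, None], 0.0)
        ols = np.linalg.lstsq(d.D, X, rcond=None)[0]
        assert np.max(np.abs(W[:, 0] - ols)) < 1e-6

    def test_linearity_in_response_amplitude(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 2, (40, 7))
        d = pta.build_design(P, resolution_ms=10)
        X = d.D @ rng.normal(0, 1, 28) + rng.standard_normal(d.D.shape[0])
        r1 = pta.fit_pta(X, d, lambda_prime=1.0)
        r2 = pta.fit_pta(2.0 * X, d, lambda_prime=1.0)
        np.testing.assert_allclose(r2.curves, 2.0 * r1.curves, atol=1e-10)

    def test_normalized_curve_peak_is_one(self):
        rng = np.random.default_rng(6)
        P = rng.normal(0, 2, (40, 7))
        d = pta.build_design(P, resolution_ms=10)
        X = d.D @ rng.normal(0, 1, 28)
        res = pta.fit_pta(X, d)
        assert np.max(np.abs(res.normalized_curves)) == pytest.approx(1.0)

    def test_constant_gain_gives_flat_peaks(self):
        # response is the same unit-strength bump for every pulse
        rng = np.random.default_rng(7)
        P = rng.normal(0, 2, (200, 7))
        d = pta.build_design(P, resolution_ms=10)
        w_true = np.tile([0.0, 1.0, 1.0, 0.0], 7)  # identical per pulse
        X = d.D @ w_true + 0.3 * rng.standard_normal(d.D.shape[0])
        res = pta.fit_pta(X, d)
        peaks = res.normalized_curves.max(axis=1)[:, 0]
        assert peaks.std() / peaks.mean() < 0.1

    def test_all_zero_design_rejected(self):
        d = pta.build_design(np.zeros((5, 7)), resolution_ms=10)
        with pytest.raises(ValueError, match="all-zero design"):
            pta.fit_pta(np.zeros(d.D.shape[0]), d)


class TestExponentialFit:
    def test_exact_exponential_recovered(self):
        idx = np.arange(1, 8)
        peaks = 0.86 * np.exp(-0.09 * idx)
        fit = pta.fit_exponential(peaks)
        assert fit.a == pytest.approx(0.86, abs=1e-6)
        assert fit.b == pytest.approx(-0.09, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_peaks_give_zero_decay(self):
        fit = pta.fit_exponential(np.full(7, 0.5))
        assert fit.b == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_u_shaped_peaks_fit_poorly(self):
        peaks = np.array([1.0, 0.6, 0.4, 0.35, 0.4, 0.6, 1.0])
        fit = pta.fit_exponential(peaks)
        assert fit.r_squared < 0.5

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            pta.fit_exponential(np.ones(6))
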