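import numpy as np
import pytest

from pulsepop import choicemap, synth


def _weak_subset(fs, min_trials=50):
    weak = choicemap.select_weak_trials(
        fs.pulse_values.sum(1), fs.correct, min_trials=min_trials
    )
    return weak.trial_ids


class TestWeakTrialSelection:
    def test_zero_coherence_always_included_first(self):
        net = np.array([0, 0, 3, -3, 6, -6])
        correct = np.array([1, 0, 1, 1, 1, 1])  # nonzero levels at ceiling
        ws = choicemap.select_weak_trials(net, correct, min_trials=1)
        assert 0.0 in ws.coherence_levels_included
        np.testing.assert_array_equal(ws.trial_ids, [0, 1])

    def test_ceiling_session_keeps_only_zero_level(self):
        rng = np.random.default_rng(0)
        net = np.concatenate([np.zeros(60), rng.choice([2, -2, 4, -4], 200)])
        correct = np.concatenate([rng.integers(0, 2, 60), np.ones(200)])
        ws = choicemap.select_weak_trials(net, correct, min_trials=10)
        np.testing.assert_array_equal(ws.coherence_levels_included, [0.0])
        assert ws.accuracy < 0.65

    def test_small_session_flagged_excluded(self):
        net = np.zeros(80)
        correct = np.random.default_rng(1).integers(0, 2, 80)
        ws = choicemap.select_weak_trials(net, correct)
        assert ws.excluded  # < 100 weak trials

    def test_realistic_session_accuracy_below_threshold(self):
        fs = synth.simulate_factor_session(n_trials=600, rng=2)
        ws = choicemap.select_weak_trials(fs.pulse_values.sum(1), fs.correct)
        assert ws.accuracy < 0.65
        assert len(ws.trial_ids) >= 100


class TestResidualize:
    def test_zero_pulses_give_centered_factors(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 6, 3))
        res = choicemap.residualize(X, np.zeros((50, 7)))
        np.testing.assert_allclose(res.residuals, X - X.mean(0), atol=1e-12)

    def test_huge_ridge_approaches_centered_factors(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4, 2))
        P = rng.normal(0, 2, (50, 7))
        res = choicemap.residualize(X, P, lambda_tilde=1e12)
        np.testing.assert_allclose(res.residuals, X - X.mean(0), atol=1e-6)

    def test_linear_pulse_component_removed(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 2, (500, 7))
        W = rng.standard_normal((7, 4 * 2))
        X = (P @ W).reshape(500, 4, 2) + 0.5 * rng.standard_normal((500, 4, 2))
        res = choicemap.residualize(X, P)
        for t in range(4):
            for k in range(2):
                for i in range(7):
                    r = np.corrcoef(res.residuals[:, t, k], P[:, i])[0, 1]
                    assert abs(r) < 0.05

    def test_rebin_sums_and_drops_partial_bins(self):
        X = np.arange(2 * 25 * 1, dtype=float).reshape(2, 25, 1)
        out = choicemap.rebin_factors(X, bin_s=0.01, target_bin_s=0.1)
        assert out.shape == (2, 2, 1)
        assert out[0, 0, 0] == X[0, :10, 0].sum()


class TestChoiceDecoder:
    def test_wrong_fold_count_rejected(self):
        rng = np.random.default_rng(6)
        X, y = rng.standard_normal((60, 3)), rng.integers(0, 2, 60)
        with pytest.raises(ValueError, match="fixed at 5"):
            choicemap.fit_choice_decoder(X, y, n_folds=2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            choicemap.fit_choice_decoder(np.random.rand(30, 2), np.ones(30))

    def test_every_mapping_value_is_out_of_fold(self):
        rng = np.random.default_rng(7)
        X, y = rng.standard_normal((80, 3)), rng.integers(0, 2, 80)
        _, mapping = choicemap.fit_choice_decoder(X, y)
        assert np.all(mapping.fold_id >= 0)
        assert np.all((mapping.c >= 0) & (mapping.c <= 1))

    def test_null_residuals_give_chance_cv_accuracy(self):
        rng = np.random.default_rng(8)
        X, y = rng.standard_normal((300, 4)), rng.integers(0, 2, 300)
        _, mapping = choicemap.fit_choice_decoder(X, y)
        cp = choicemap.pooled_cp(mapping.c, y, mapping.fold_id)
        assert abs(cp - 0.5) < 0.12

    def test_injected_loading_direction_recovered(self):
        rng = np.random.default_rng(9)
        direction = np.array([0.8, -0.6, 0.0])
        y = rng.integers(0, 2, 500)
        X = rng.standard_normal((500, 3)) + np.outer(2.0 * y - 1.0, direction)
        decoder, _ = choicemap.fit_choice_decoder(X, y)
        cos = decoder.beta @ direction / (
            np.linalg.norm(decoder.beta) * np.linalg.norm(direction)
        )
        assert cos >= 0.9

    def test_zero_decoder_maps_to_half(self):
        dec = choicemap.ChoiceDecoder(
            beta=np.zeros(3), beta0=0.0, lambda_hat=1.0, cv_folds=5,
            mean=np.zeros(3), scale=np.ones(3),
        )
        c = choicemap.choice_mapping(dec, np.random.rand(10, 3))
        np.testing.assert_allclose(c, 0.5)

    def test_cp_invariant_to_sigmoid_transform(self):
        # ROC invariance: CP on c equals CP on the linear score exactly
        rng = np.random.default_rng(10)
        dec = choicemap.ChoiceDecoder(
            beta=rng.standard_normal(3), beta0=0.3, lambda_hat=1.0, cv_folds=5,
            mean=np.zeros(3), scale=np.ones(3),
        )
        X = rng.standard_normal((100, 3))
        y = rng.integers(0, 2, 100)
        score = X @ dec.beta + dec.beta0
        c = choicemap.choice_mapping(dec, X)
        assert choicemap.pooled_cp(c, y) == choicemap.pooled_cp(score, y)


class TestCpTimecourses:
    def test_fixed_and_dynamic_agree_for_static_axis(self):
        fs = synth.simulate_factor_session(
            n_trials=500, choice_amplitude=0.25,
            choice_course=lambda t: np.ones_like(t), rng=11,
        )
        ids = _weak_subset(fs)
        resid = choicemap.residualize(fs.factors[ids][:, :12], fs.pulse_values[ids])
        fixed = choicemap.cp_fixed_readout(
            resid, fs.choices[ids], epoch_bins=slice(0, 12), axis="all"
        )
        dynamic = choicemap.cp_dynamic_readout(resid, fs.choices[ids], axis="all")
        assert np.nanmax(np.abs(fixed.cp - dynamic.cp)) < 0.12

    def test_stimulus_axis_cp_near_half_without_choice_signal(self):
        fs = synth.simulate_factor_session(n_trials=400, choice_amplitude=0.0, rng=12)
        ids = _weak_subset(fs)
        resid = choicemap.residualize(fs.factors[ids][:, :12], fs.pulse_values[ids])
        cp = choicemap.cp_fixed_readout(
            resid, fs.choices[ids], epoch_bins=slice(0, 12), axis="stimulus"
        )
        assert np.nanmean(np.abs(cp.cp - 0.5)) < 0.08

    def test_rt_split_contract(self):
        fs = synth.simulate_factor_session(n_trials=60, choice_amplitude=0.2, rng=13)
        ids = np.arange(8)  # far too few trials per half
        resid = choicemap.residualize(fs.factors[ids][:, :5], fs.pulse_values[ids])
        with pytest.raises(ValueError, match="too few trials"):
            choicemap.cp_by_rt_split(resid, fs.choices[ids], fs.rt_s[ids])

    def test_nonstimulus_axis_requires_k_over_one(self):
        with pytest.raises(ValueError):
            choicemap._axis_columns(1, "nonstimulus")
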