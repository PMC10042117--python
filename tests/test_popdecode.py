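import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsepop import popdecode, synth
from pulsepop.synth import SessionBundle


def _mini_bundle(spike_rows, n_trials=2, n_units=1):
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "condition": "flat",
            "mu_index": 0,
            "choice": np.zeros(n_trials, int),
            "correct": np.zeros(n_trials, int),
            "rt_s": 0.3,
            "t_stim_on": 0.0,
            "t_stim_off": 1.05,
            "t_fix_off": 1.65,
            "t_sacc": 1.95,
            "t_reward": 2.25,
            "t_targets_on": -0.7,
            "frozen": 0,
        }
    )
    pulses = pd.DataFrame(
        [(t, i + 1, 0) for t in range(n_trials) for i in range(7)],
        columns=["trial_id", "pulse_index", "value"],
    )
    spikes = pd.DataFrame(spike_rows, columns=["trial_id", "unit_id", "time_s"])
    units = pd.DataFrame(
        {"unit_id": np.arange(n_units), "d_prime": 0.0, "pref_sign": 1}
    )
    return SessionBundle(trials=trials, pulses=pulses, spikes=spikes, units=units)


class TestCounting:
    def test_empty_spike_table_gives_zero_counts(self):
        b = _mini_bundle([])
        assert popdecode.count_trial_spikes(b).sum() == 0

    def test_window_is_half_open(self):
        b = _mini_bundle([(0, 0, 1.19), (0, 0, 1.21), (0, 0, -0.01)])
        counts = popdecode.count_trial_spikes(b)
        assert counts[0, 0] == 1  # only the 1.19 s spike falls in [0, 1.2)

    def test_poisson_rate_yields_expected_mean_count(self):
        rng = np.random.default_rng(0)
        rate, n_trials = 25.0, 300
        rows = []
        for t in range(n_trials):
            n = rng.poisson(rate * 1.2)
            rows += [(t, 0, u) for u in rng.uniform(0, 1.2, n)]
        b = _mini_bundle(rows, n_trials=n_trials)
        mean = popdecode.count_trial_spikes(b)[:, 0].mean()
        assert abs(mean - 1.2 * rate) < 4 * np.sqrt(1.2 * rate / n_trials)


class TestRocAuc:
    def test_identical_distributions_give_half(self):
        assert popdecode.roc_auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_full_separation_gives_one(self):
        assert popdecode.roc_auc([1, 2], [5, 6]) == 1.0

    def test_tie_counting_example(self):
        assert popdecode.roc_auc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            popdecode.roc_auc([], [1.0])

    @given(
        a=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_complement_symmetry_and_monotone_invariance(self, a, b):
        auc = popdecode.roc_auc(a, b)
        assert auc + popdecode.roc_auc(b, a) == pytest.approx(1.0)
        f = lambda v: np.exp(0.5 * np.asarray(v, float)) + 3.0  # strictly increasing
        assert popdecode.roc_auc(f(a), f(b)) == pytest.approx(auc)


class TestDecoder:
    def test_perfectly_separating_unit(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        counts = np.column_stack([labels * 10 + rng.poisson(1, 100)])
        model = popdecode.fit_decoder(counts, labels, "direction")
        assert model.weights[0] > 0
        pred = (counts @ model.weights + model.intercept) > 0
        assert np.array_equal(pred.astype(int), labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            popdecode.fit_decoder(np.random.rand(20, 2), np.zeros(20), "choice")

    def test_shuffled_labels_give_chance_cv_accuracy(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(10.0, size=(400, 8)).astype(float)
        labels = rng.integers(0, 2, 400)
        accs = []
        folds = np.array_split(rng.permutation(400), 5)
        for f in folds:
            train = np.setdiff1d(np.arange(400), f)
            m = popdecode.fit_decoder(counts, labels, "choice", train)
            pred = (counts[f] @ m.weights + m.intercept) > 0
            accs.append((pred.astype(int) == labels[f]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.1  # ~2 binomial SD at n=400

    def test_weight_ground_truth_dissociation(self, spike_session):
        # direction weights track the simulated direction gain; choice
        # weights (frozen trials only) track the choice loading instead
        dg = np.array(spike_session.config["direction_gain"])
        cl = np.array(spike_session.config["choice_loading"])
        ddec = popdecode.fit_direction_decoder(spike_session)
        cdec = popdecode.fit_choice_decoder_counts(spike_session)
        assert np.corrcoef(ddec.weights, dg)[0, 1] > 0.7
        assert np.corrcoef(ddec.weights, dg)[0, 1] > abs(
            np.corrcoef(ddec.weights, cl)[0, 1]
        )
        assert np.corrcoef(cdec.weights, cl)[0, 1] > abs(
            np.corrcoef(cdec.weights, dg)[0, 1]
        )

    def test_few_frozen_trials_warns(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, (10, 20)).astype(float)
        labels = rng.integers(0, 2, 10)
        labels[:2] = [0, 1]
        with pytest.warns(UserWarning, match="ill-posed"):
            popdecode.fit_decoder(counts, labels, "choice")


class TestProjection:
    def test_zero_weights_give_flat_zero(self, small_session):
        model = popdecode.fit_direction_decoder(small_session)
        zero = popdecode.DecoderModel(
            weights=np.zeros_like(model.weights), intercept=0.0,
            target="direction", count_window=model.count_window,
            training_trials=model.training_trials, lam=model.lam,
        )
        proj = popdecode.project_rates(zero, small_session)
        assert np.all(proj.values == 0.0)

    def test_single_unit_weight_one_equals_smoothed_rate(self, small_session):
        w = np.zeros(small_session.n_units)
        w[2] = 1.0
        model = popdecode.DecoderModel(
            weights=w, intercept=0.0, target="direction",
            count_window=(0.0, 1.2), training_trials=np.arange(1), lam=0.0,
        )
        proj = popdecode.project_rates(model, small_session)
        rates, _ = popdecode.binned_rates(small_session, (0.0, 1.2))
        from pulsepop._util import boxcar_smooth

        expected = boxcar_smooth(rates[:, 2, :], 5, axis=-1)
        np.testing.assert_allclose(proj.values, expected, atol=1e-12)

    def test_boxcar_preserves_constant_rate(self):
        from pulsepop._util import boxcar_smooth

        const = np.full((3, 40), 7.0)
        np.testing.assert_allclose(boxcar_smooth(const, 5), const)


class TestCpTimecourse:
    def test_choices_equal_thresholded_projection_give_cp_one(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(80, 10))
        proj = popdecode.ProjectedRates(
            values=values, times=np.arange(10) * 0.01, bin_s=0.01,
            smoothing_s=0.05, alignment="stimulus",
        )
        choices = (values[:, 0] > 0).astype(int)
        cp = popdecode.cp_timecourse(proj, choices)
        assert cp.cp[0] == 1.0

    def test_independent_choices_stay_near_half(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(200, 50))
        proj = popdecode.ProjectedRates(
            values=values, times=np.arange(50) * 0.01, bin_s=0.01,
            smoothing_s=0.05, alignment="stimulus",
        )
        choices = rng.integers(0, 2, 200)
        cp = popdecode.cp_timecourse(proj, choices)
        # permutation-scale band: SE of ROC at n~100/100 is ~0.04
        assert np.mean(np.abs(cp.cp - 0.5) < 0.1) >= 0.95

    def test_single_class_yields_nan_not_half(self):
        proj = popdecode.ProjectedRates(
            values=np.random.rand(5, 4), times=np.arange(4) * 0.01,
            bin_s=0.01, smoothing_s=0.05, alignment="stimulus",
        )
        cp = popdecode.cp_timecourse(proj, np.ones(5, int))
        assert np.all(np.isnan(cp.cp))

    def test_injected_late_latent_raises_late_cp_only(self, spike_session):
        frozen = spike_session.trials["frozen"].to_numpy() == 1
        choices = spike_session.trials["choice"].to_numpy()
        cdec = popdecode.fit_choice_decoder_counts(spike_session)
        proj = popdecode.project_rates(cdec, spike_session)
        sub = popdecode.ProjectedRates(
            values=proj.values[frozen], times=proj.times, bin_s=proj.bin_s,
            smoothing_s=proj.smoothing_s, alignment=proj.alignment,
        )
        cp = popdecode.cp_timecourse(sub, choices[frozen])
        early = np.nanmean(cp.cp[proj.times < 0.4])
        late = np.nanmean(cp.cp[proj.times > 0.8])
        assert late > early + 0.05
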