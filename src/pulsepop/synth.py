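"""Synthetic sessions with known ground truth.

No public recordings exist for this task, so every analysis stage is
validated against simulated sessions in which the quantities the analyses
estimate are known exactly:

* choices come from a logistic observer with a known 7-weight temporal
  kernel (the psychophysical-kernel ground truth);
* spikes come from an inhomogeneous-Poisson population with exponential
  link, a known time-varying stimulus gain ``g(t)`` (the pulse-triggered-
  average ground truth) and an injectable low-rank choice-correlated latent
  (the choice-probability ground truth).

The simulator mirrors the trial structure of the experiment: seven 150 ms
pulses (1050 ms of motion), fixation offset 500-1000 ms after motion
offset, a saccade after a lognormal reaction time, and reward shortly
after. Spike times are generated at 1 ms resolution between target onset
and reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import stimgen
from .stimgen import N_PULSES, PULSE_DUR_S, PulseSequence

STIM_DUR_S = N_PULSES * PULSE_DUR_S  # 1.05 s

#: spike-count window used by the trial-count decoders, [0, 1.2) s
COUNT_WINDOW_S = (0.0, STIM_DUR_S + 0.150)


@dataclass(frozen=True)
class ObserverSpec:
    """Logistic observer: P(choice=1) = lapse + (1-2*lapse)*sigmoid(b + w.s)."""

    kernel_true: np.ndarray
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self) -> None:
        kernel = np.asarray(self.kernel_true, dtype=float)
        if kernel.shape != (N_PULSES,):
            raise ValueError("kernel_true must have 7 weights")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")
        object.__setattr__(self, "kernel_true", kernel)


def early_weighted_kernel(scale: float = 0.35) -> np.ndarray:
    """A canonical early-weighted temporal kernel (pulse 1 dominates)."""
    return scale * np.array([1.0, 0.8, 0.5, 0.3, 0.15, 0.07, 0.03])


def flat_kernel(scale: float = 0.2) -> np.ndarray:
    return np.full(N_PULSES, scale)


def simulate_choices(
    pulse_values: np.ndarray,
    observer: ObserverSpec,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw binary choices (1 = positive direction) for each trial."""
    pulse_values = np.asarray(pulse_values, dtype=float)
    if pulse_values.ndim != 2 or pulse_values.shape[1] != N_PULSES:
        raise ValueError("pulse_values must be (n_trials, 7)")
    rng = np.random.default_rng(rng)
    logit = observer.bias + pulse_values @ observer.kernel_true
    p = observer.lapse + (1.0 - 2.0 * observer.lapse) / (1.0 + np.exp(-logit))
    return (rng.random(len(p)) < p).astype(int)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

def constant_gain(t: np.ndarray) -> np.ndarray:
    return np.ones_like(t)


def u_shaped_gain(t: np.ndarray) -> np.ndarray:
    """U-shaped stimulus gain over the 1.05 s stimulus: high at both ends."""
    mid = STIM_DUR_S / 2.0
    return 0.4 + 0.6 * ((t - mid) / mid) ** 2


def decaying_gain(t: np.ndarray, tau: float = 1.2) -> np.ndarray:
    """Exponentially decaying gain, the profile typical of adaptation."""
    return np.exp(-t / tau)


def late_choice_course(
    t: np.ndarray, onset: float = 0.65, width: float = 0.08
) -> np.ndarray:
    """Choice latent rising late in the stimulus and sustained afterwards."""
    return 1.0 / (1.0 + np.exp(-(t - onset) / width))


def windowed_choice_course(start: float, stop: float) -> Callable[[np.ndarray], np.ndarray]:
    """Choice latent equal to 1 on [start, stop) seconds and 0 elsewhere."""

    def course(t: np.ndarray) -> np.ndarray:
        return ((t >= start) & (t < stop)).astype(float)

    return course


@dataclass
class PopulationSpec:
    """Poisson population with exponential link.

    Per-unit log-rate at time ``t`` (seconds from stimulus onset)::

        log r_n(t) = log(baseline_n)
                     + direction_gain_n * g(t) * drive(t - latency)
                     + choice_loading_n * (2*choice - 1) * c(t)

    where ``drive`` holds the active pulse strength (signal elements) during
    each 150 ms pulse epoch, ``g`` is the dimensionless stimulus-gain
    profile over the stimulus period, and ``c`` is the shared
    choice-latent time course (rank-1 choice structure by default).
    """

    n_units: int = 20
    baseline_rate: np.ndarray | None = None  # spikes/s
    direction_gain: np.ndarray | None = None  # log-rate per signal element
    choice_loading: np.ndarray | None = None
    gain_profile: Callable[[np.ndarray], np.ndarray] = constant_gain
    choice_latent_course: Callable[[np.ndarray], np.ndarray] = late_choice_course
    choice_amplitude: float = 0.0
    latency_s: float = 0.050
    max_rate: float = 500.0

    def realize(self, rng: np.random.Generator) -> "PopulationSpec":
        """Fill in any unset per-unit parameters from their default priors."""
        n = self.n_units
        if self.baseline_rate is None:
            self.baseline_rate = rng.uniform(5.0, 30.0, size=n)
        if self.direction_gain is None:
            # magnitudes chosen so per-unit direction d' spans ~0.2-1.5,
            # the range typical of direction-selective MT units
            signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            self.direction_gain = signs * np.abs(rng.normal(0.06, 0.02, size=n))
        if self.choice_loading is None:
            raw = rng.normal(size=n)
            raw /= np.linalg.norm(raw)
            self.choice_loading = self.choice_amplitude * raw
        self.baseline_rate = np.asarray(self.baseline_rate, dtype=float)
        if np.any(self.baseline_rate < 0):
            raise ValueError("baseline rates must be non-negative")
        self.direction_gain = np.asarray(self.direction_gain, dtype=float)
        self.choice_loading = np.asarray(self.choice_loading, dtype=float)
        return self


def _stimulus_drive(t: np.ndarray, pulses: np.ndarray, latency_s: float) -> np.ndarray:
    """Active pulse strength at each time, shifted by the response latency."""
    shifted = t - latency_s
    idx = np.floor(shifted / PULSE_DUR_S).astype(int)
    active = (shifted >= 0) & (shifted < STIM_DUR_S)
    drive = np.zeros_like(t)
    drive[active] = pulses[idx[active]]
    return drive


def simulate_spikes(
    pulse_values: np.ndarray,
    choices: np.ndarray,
    pop: PopulationSpec,
    t_start: np.ndarray,
    t_stop: np.ndarray,
    rng: np.random.Generator | int | None = None,
    bin_s: float = 0.001,
) -> pd.DataFrame:
    """Simulate spike times for every trial and unit.

    Times are seconds relative to stimulus onset; trial ``i`` is simulated
    over ``[t_start[i], t_stop[i])`` as an inhomogeneous Poisson process
    discretized at 1 ms.
    """
    pulse_values = np.asarray(pulse_values, dtype=float)
    choices = np.asarray(choices)
    if len(choices) != len(pulse_values):
        raise ValueError("choices and pulse_values must have equal length")
    rng = np.random.default_rng(rng)
    pop.realize(rng)
    log_base = np.log(np.maximum(pop.baseline_rate, 1e-12))
    rows: list[tuple[int, int, float]] = []
    for trial in range(len(pulse_values)):
        t = np.arange(t_start[trial], t_stop[trial], bin_s)
        drive = _stimulus_drive(t, pulse_values[trial], pop.latency_s)
        in_stim = (t >= 0) & (t < STIM_DUR_S)
        gain = np.zeros_like(t)
        gain[in_stim] = pop.gain_profile(t[in_stim])
        latent = pop.choice_latent_course(t)
        sign = 2.0 * choices[trial] - 1.0
        # (n_units, n_bins) log-rate
        log_rate = (
            log_base[:, None]
            + pop.direction_gain[:, None] * (gain * drive)[None, :]
            + pop.choice_loading[:, None] * (sign * latent)[None, :]
        )
        rate = np.minimum(np.exp(log_rate), pop.max_rate)
        counts = rng.poisson(rate * bin_s)
        unit_idx, bin_idx = np.nonzero(counts)
        for u, b in zip(unit_idx, bin_idx):
            for _ in range(counts[u, b]):
                rows.append((trial, int(u), float(t[b] + rng.uniform(0, bin_s))))
    spikes = pd.DataFrame(rows, columns=["trial_id", "unit_id", "time_s"])
    return spikes.sort_values(["trial_id", "unit_id", "time_s"], ignore_index=True)


# ---------------------------------------------------------------------------
# full session bundles
# ---------------------------------------------------------------------------

@dataclass
class SessionBundle:
    """One session: trials, pulses, spikes and unit metadata.

    All times are seconds relative to stimulus onset of the same trial.
    """

    trials: pd.DataFrame
    pulses: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def pulse_matrix(self) -> np.ndarray:
        return stimgen.pulse_matrix(self.pulses)


def _empirical_dprime(counts: np.ndarray, net_sign: np.ndarray) -> np.ndarray:
    """Per-unit d' between positive- and negative-direction trials."""
    pos, neg = counts[net_sign > 0], counts[net_sign < 0]
    if len(pos) < 2 or len(neg) < 2:
        return np.zeros(counts.shape[1])
    pooled = np.sqrt(0.5 * (pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (pos.mean(axis=0) - neg.mean(axis=0)) / pooled
    return np.nan_to_num(d)


def simulate_session(
    n_trials: int,
    condition: str = "flat",
    observer: ObserverSpec | None = None,
    pop: PopulationSpec | None = None,
    rng: np.random.Generator | int | None = None,
    frozen_fraction: float = 0.05,
    mu_levels: Sequence[float] = stimgen.DEFAULT_MU_LEVELS,
    pulse_sd: float = stimgen.DEFAULT_PULSE_SD,
    rt_median_s: float = 0.29,
    rt_sigma: float = 0.30,
    spike_window: str = "targets_to_reward",
) -> SessionBundle:
    """Simulate one complete session.

    ``spike_window`` selects the simulated spike support: the full
    ``"targets_to_reward"`` window needed by latent-factor analyses, or the
    cheaper ``"stimulus"`` window ([-0.2, 1.3] s) sufficient for the
    count decoders.
    """
    rng = np.random.default_rng(rng)
    observer = observer or ObserverSpec(kernel_true=early_weighted_kernel())
    pop = pop or PopulationSpec()
    sequences = stimgen.generate_session_stimuli(
        n_trials,
        condition,
        mu_levels=tuple(mu_levels),
        frozen_fraction=frozen_fraction,
        pulse_sd=pulse_sd,
        rng=rng,
    )
    pulses = stimgen.pulses_to_frame(sequences)
    pulse_values = np.array([s.values for s in sequences], dtype=float)
    frozen = np.array([s.frozen for s in sequences])
    mu_index = np.array([s.mu_index for s in sequences])
    choices = simulate_choices(pulse_values, observer, rng)

    # event times, jittered uniformly within the task's stated ranges
    t_targets_on = -rng.uniform(0.5, 1.0, size=n_trials)
    t_stim_on = np.zeros(n_trials)
    t_stim_off = np.full(n_trials, STIM_DUR_S)
    t_fix_off = t_stim_off + rng.uniform(0.5, 1.0, size=n_trials)
    rt_s = np.clip(
        rng.lognormal(np.log(rt_median_s), rt_sigma, size=n_trials), 0.08, 0.6
    )
    t_sacc = t_fix_off + rt_s
    t_reward = t_sacc + 0.3

    net = pulse_values.sum(axis=1)
    correct = np.where(
        net == 0,
        rng.integers(0, 2, size=n_trials),  # zero-sum trials rewarded at random
        (choices == (net > 0).astype(int)).astype(int),
    )

    if spike_window == "targets_to_reward":
        t0, t1 = t_targets_on, t_reward
    elif spike_window == "stimulus":
        t0 = np.full(n_trials, -0.2)
        t1 = np.full(n_trials, COUNT_WINDOW_S[1] + 0.1)
    else:
        raise ValueError(f"unknown spike_window {spike_window!r}")
    spikes = simulate_spikes(pulse_values, choices, pop, t0, t1, rng)

    counts = np.zeros((n_trials, pop.n_units))
    in_win = (spikes["time_s"] >= COUNT_WINDOW_S[0]) & (
        spikes["time_s"] < COUNT_WINDOW_S[1]
    )
    grouped = spikes[in_win].groupby(["trial_id", "unit_id"]).size()
    for (t, u), c in grouped.items():
        counts[t, u] = c
    dprime = _empirical_dprime(counts, np.sign(net))

    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "condition": condition,
            "mu_index": mu_index,
            "choice": choices,
            "correct": correct,
            "rt_s": rt_s,
            "t_stim_on": t_stim_on,
            "t_stim_off": t_stim_off,
            "t_fix_off": t_fix_off,
            "t_sacc": t_sacc,
            "t_reward": t_reward,
            "t_targets_on": t_targets_on,
            "frozen": frozen.astype(int),
        }
    )
    units = pd.DataFrame(
        {
            "unit_id": np.arange(pop.n_units),
            "d_prime": dprime,
            "pref_sign": np.sign(pop.direction_gain).astype(int),
        }
    )
    config = {
        "condition": condition,
        "n_trials": n_trials,
        "observer_kernel": observer.kernel_true.tolist(),
        "observer_bias": observer.bias,
        "observer_lapse": observer.lapse,
        "baseline_rate": pop.baseline_rate.tolist(),
        "direction_gain": pop.direction_gain.tolist(),
        "choice_loading": pop.choice_loading.tolist(),
        "choice_amplitude": pop.choice_amplitude,
        "latency_s": pop.latency_s,
    }
    return SessionBundle(trials=trials, pulses=pulses, spikes=spikes, units=units, config=config)


# ---------------------------------------------------------------------------
# factor-level sessions (for choice analyses without a spike-level fit)
# ---------------------------------------------------------------------------

@dataclass
class FactorSession:
    """Latent-factor trajectories with trial metadata, stimulus-aligned.

    ``factors`` has shape (n_trials, n_bins, K) on a uniform grid starting
    at ``t0_s`` with bin width ``bin_s``; factor 0 is the stimulus axis.
    """

    factors: np.ndarray
    bin_s: float
    t0_s: float
    pulse_values: np.ndarray
    choices: np.ndarray
    correct: np.ndarray
    rt_s: np.ndarray
    t_sacc: np.ndarray
    choice_loading: np.ndarray

    @property
    def times(self) -> np.ndarray:
        """Bin-center times, seconds from stimulus onset."""
        return self.t0_s + (np.arange(self.factors.shape[1]) + 0.5) * self.bin_s


def simulate_factor_session(
    n_trials: int = 300,
    n_factors: int = 4,
    condition: str = "flat",
    choice_amplitude: float = 0.0,
    choice_course: Callable[[np.ndarray], np.ndarray] | None = None,
    choice_course_long_rt: Callable[[np.ndarray], np.ndarray] | None = None,
    choice_course_align: str = "stimulus",
    stimulus_scale: float = 0.08,
    noise_sd: float = 0.5,
    bin_s: float = 0.1,
    t_end_s: float = 2.6,
    observer: ObserverSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> FactorSession:
    """Generate latent-factor trajectories directly from the task model.

    Factor 0 carries the pulse drive (stimulus axis); factors 1..K-1 carry
    the choice latent through a random unit-norm loading scaled by
    ``choice_amplitude``, plus smooth noise. The latent time course is
    evaluated in stimulus time by default, or locked to each trial's
    saccade with ``choice_course_align="saccade"`` (its argument is then
    time-to-saccade, negative before the movement). Passing a separate
    ``choice_course_long_rt`` lets the latent onset differ between RT
    halves (used to probe the saccade-aligned CP timing analysis).
    """
    rng = np.random.default_rng(rng)
    observer = observer or ObserverSpec(kernel_true=flat_kernel())
    sequences = stimgen.generate_session_stimuli(
        n_trials, condition, frozen_fraction=0.05, rng=rng
    )
    pulse_values = np.array([s.values for s in sequences], dtype=float)
    choices = simulate_choices(pulse_values, observer, rng)
    net = pulse_values.sum(axis=1)
    correct = np.where(
        net == 0,
        rng.integers(0, 2, size=n_trials),
        (choices == (net > 0).astype(int)).astype(int),
    )
    rt_s = np.clip(rng.lognormal(np.log(0.29), 0.30, size=n_trials), 0.08, 0.6)
    t_fix_off = STIM_DUR_S + rng.uniform(0.5, 1.0, size=n_trials)
    t_sacc = t_fix_off + rt_s

    n_bins = int(round(t_end_s / bin_s))
    times = (np.arange(n_bins) + 0.5) * bin_s
    drive = np.zeros((n_trials, n_bins))
    for i in range(N_PULSES):
        in_pulse = (times >= i * PULSE_DUR_S) & (times < (i + 1) * PULSE_DUR_S)
        drive[:, in_pulse] += pulse_values[:, [i]]
    course = choice_course or late_choice_course
    if choice_course_align == "saccade":
        latent = np.stack([course(times - ts) for ts in t_sacc])
    elif choice_course_align == "stimulus":
        latent = np.tile(course(times), (n_trials, 1))
    else:
        raise ValueError(f"unknown choice_course_align {choice_course_align!r}")
    if choice_course_long_rt is not None:
        long_rt = rt_s > np.median(rt_s)
        if choice_course_align == "saccade":
            latent[long_rt] = np.stack(
                [choice_course_long_rt(times - ts) for ts in t_sacc[long_rt]]
            )
        else:
            latent[long_rt] = choice_course_long_rt(times)

    loading = np.zeros(n_factors)
    if n_factors > 1:
        raw = rng.normal(size=n_factors - 1)
        loading[1:] = raw / np.linalg.norm(raw)
    else:
        loading[0] = 1.0
    loading *= choice_amplitude

    sign = (2.0 * choices - 1.0)[:, None]
    factors = rng.normal(0.0, noise_sd, size=(n_trials, n_bins, n_factors))
    # mild temporal smoothing so the noise has realistic autocorrelation
    kernel = np.array([0.25, 0.5, 0.25])
    factors = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), 1, factors
    )
    factors[:, :, 0] += stimulus_scale * drive
    factors += (sign * latent)[:, :, None] * loading[None, None, :]
    return FactorSession(
        factors=factors,
        bin_s=bin_s,
        t0_s=0.0,
        pulse_values=pulse_values,
        choices=choices,
        correct=correct,
        rt_s=rt_s,
        t_sacc=t_sacc,
        choice_loading=loading,
    )
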