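"""Motion-pulse stimulus generation.

The stimulus of one trial is a sequence of seven 150 ms motion pulses. The
strength of pulse *i* is the signed number of coherently drifting signal
elements (out of 19 Gabor elements on a hexagonal grid); positive values
drift one way, negative the other. Per-pulse strengths are drawn from a
Gaussian whose mean follows one of three temporal schedules:

``flat``
    the mean equals ``mu_k`` for all seven pulses;
``late``
    the mean starts at 0 on pulse 1 and ramps up to ``mu_k`` by pulse 7
    along a logistic transition (midpoint 4 pulses, slope 0.3);
``early``
    the exact time-reversal of ``late``.

Each session also contains "frozen noise" trials: one fixed, zero-net-motion
sequence repeated identically, used downstream to measure choice-conditioned
variability with the stimulus held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_PULSES = 7
N_ELEMENTS = 19
PULSE_DUR_S = 0.150

CONDITIONS = ("flat", "late", "early")

#: default signed trial-type means, in signal elements (strong left, weak
#: left, zero-mean, weak right, strong right)
DEFAULT_MU_LEVELS = (-3.0, -1.0, 0.0, 1.0, 3.0)

#: default per-pulse Gaussian s.d., in signal elements
DEFAULT_PULSE_SD = 1.5


@dataclass(frozen=True)
class PulseSchedule:
    """Per-pulse mean motion strengths for one trial type and condition."""

    condition: str
    mu_k: float
    per_pulse_mean: np.ndarray
    mu_index: int = 0
    transition_midpoint: float = 4.0
    transition_slope: float = 0.3

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.per_pulse_mean) != N_PULSES:
            raise ValueError("schedule must have exactly 7 pulses")


@dataclass(frozen=True)
class PulseSequence:
    """The seven signed pulse strengths of one trial."""

    values: np.ndarray
    frozen: bool = False
    mu_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != (N_PULSES,):
            raise ValueError("pulse sequence must have exactly 7 values")
        if np.any(np.abs(values) > N_ELEMENTS):
            raise ValueError(f"pulse values cannot exceed +/-{N_ELEMENTS}")
        if self.frozen and values.sum() != 0:
            raise ValueError("frozen sequences must sum to zero")
        object.__setattr__(self, "values", values.astype(int))

    @property
    def net_direction(self) -> int:
        return int(np.sign(self.values.sum()))


def make_pulse_schedule(
    condition: str,
    mu_k: float,
    midpoint: float = 4.0,
    slope: float = 0.3,
    mu_index: int = 0,
) -> PulseSchedule:
    """Build the per-pulse mean profile for one condition and trial type.

    For the ``late`` condition the logistic ``L(i) = 1 / (1 + exp(-slope *
    (i - midpoint)))`` is rescaled affinely so that the pulse-1 mean is
    exactly 0 and the pulse-7 mean is exactly ``mu_k``; ``early`` is its
    time-reversal. The raw logistic does not hit 0/1 at the endpoints, and
    the endpoint values (0 at pulse 1, ``mu_k`` at pulse 7) are the defining
    property of the schedules, so the rescaled form is used.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    idx = np.arange(1, N_PULSES + 1, dtype=float)
    if condition == "flat":
        mean = np.full(N_PULSES, float(mu_k))
    else:
        logistic = 1.0 / (1.0 + np.exp(-slope * (idx - midpoint)))
        ramp = (logistic - logistic[0]) / (logistic[-1] - logistic[0])
        mean = mu_k * ramp
        if condition == "early":
            mean = mean[::-1].copy()
    return PulseSchedule(
        condition=condition,
        mu_k=float(mu_k),
        per_pulse_mean=mean,
        mu_index=mu_index,
        transition_midpoint=midpoint,
        transition_slope=slope,
    )


def sample_trial(
    schedule: PulseSchedule,
    pulse_sd: float = DEFAULT_PULSE_SD,
    rng: np.random.Generator | int | None = None,
) -> PulseSequence:
    """Draw one trial's pulse sequence from the schedule.

    Each pulse is drawn independently from ``Normal(mean_i, pulse_sd)``,
    rounded to the nearest integer (signal elements are discrete) and
    clipped to the +/-19-element range of the display.
    """
    if pulse_sd < 0:
        raise ValueError("pulse_sd must be non-negative")
    rng = np.random.default_rng(rng)
    draw = rng.normal(schedule.per_pulse_mean, pulse_sd)
    values = np.clip(np.rint(draw), -N_ELEMENTS, N_ELEMENTS).astype(int)
    return PulseSequence(values=values, frozen=False, mu_index=schedule.mu_index)


def make_frozen_noise(
    rng: np.random.Generator | int | None = None,
    pulse_sd: float = DEFAULT_PULSE_SD,
) -> PulseSequence:
    """Draw the session's frozen-noise sequence: zero-sum, reproducible.

    Pulses are drawn as on a zero-mean trial and then shifted/adjusted so
    the sequence sums to exactly zero (the residual after rounding is
    absorbed one element at a time, alternating across pulses).
    """
    rng = np.random.default_rng(rng)
    values = np.clip(
        np.rint(rng.normal(0.0, pulse_sd, size=N_PULSES)), -N_ELEMENTS, N_ELEMENTS
    ).astype(int)
    # push the residual sum to zero one element at a time, spreading the
    # correction over pulses to keep the profile noise-like
    i = 0
    while values.sum() != 0:
        step = -int(np.sign(values.sum()))
        if abs(values[i % N_PULSES] + step) <= N_ELEMENTS:
            values[i % N_PULSES] += step
        i += 1
    return PulseSequence(values=values, frozen=True, mu_index=0)


def generate_session_stimuli(
    n_trials: int,
    condition: str,
    mu_levels: tuple[float, ...] = DEFAULT_MU_LEVELS,
    frozen_fraction: float = 0.05,
    pulse_sd: float = DEFAULT_PULSE_SD,
    rng: np.random.Generator | int | None = None,
) -> list[PulseSequence]:
    """Generate all pulse sequences for one session.

    Non-frozen trials are assigned uniformly at random among the trial-type
    levels ``mu_levels``; a ``frozen_fraction`` of trials repeat the single
    session-level frozen sequence. Frozen trials are interleaved at random
    positions.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= frozen_fraction <= 0.2:
        raise ValueError("frozen_fraction must lie in [0, 0.2]")
    rng = np.random.default_rng(rng)
    frozen_seq = make_frozen_noise(rng, pulse_sd=pulse_sd)
    n_frozen = int(round(frozen_fraction * n_trials))
    frozen_slots = set(rng.choice(n_trials, size=n_frozen, replace=False).tolist())
    sequences: list[PulseSequence] = []
    for t in range(n_trials):
        if t in frozen_slots:
            sequences.append(frozen_seq)
            continue
        k = int(rng.integers(len(mu_levels)))
        schedule = make_pulse_schedule(condition, mu_levels[k], mu_index=k)
        sequences.append(sample_trial(schedule, pulse_sd=pulse_sd, rng=rng))
    return sequences


def pulses_to_frame(sequences: list[PulseSequence]) -> pd.DataFrame:
    """Long-format pulses table: trial_id, pulse_index (1..7), value."""
    records = [
        (t, i + 1, int(v))
        for t, seq in enumerate(sequences)
        for i, v in enumerate(seq.values)
    ]
    return pd.DataFrame(records, columns=["trial_id", "pulse_index", "value"])


def pulse_matrix(pulses: pd.DataFrame) -> np.ndarray:
    """Pivot a long-format pulses table to a (n_trials, 7) strength matrix."""
    wide = pulses.pivot(index="trial_id", columns="pulse_index", values="value")
    wide = wide.sort_index()
    if wide.shape[1] != N_PULSES or wide.isna().any().any():
        raise ValueError("each trial must have exactly 7 pulse rows")
    return wide.to_numpy(dtype=float)
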