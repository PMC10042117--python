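"""Linear population decoding and ROC choice probability.

A logistic-regression decoder maps the vector of per-unit trial spike
counts (summed from stimulus onset to 150 ms after stimulus offset) to a
binary target — the stimulus direction or the subject's choice. The
direction decoder is trained on all trials with a nonzero net pulse sum,
excluding frozen-noise trials; the choice decoder is trained only on the
zero-sum frozen-noise trials, so that the stimulus is literally identical
across its training set and any separability reflects choice alone.

The decoder weights are then applied to 10 ms binned, 50 ms boxcar
smoothed single-trial rates, yielding a one-dimensional projected
population response whose choice-conditioned distributions define a
time-resolved choice probability (CP): the area under the ROC curve, with
0.5 meaning no choice information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._util import boxcar_smooth, ridge_logistic
from .synth import COUNT_WINDOW_S, SessionBundle


@dataclass(frozen=True)
class DecoderModel:
    weights: np.ndarray  # per-unit, raw-count scale
    intercept: float
    target: str  # "direction" | "choice"
    count_window: tuple[float, float]
    training_trials: np.ndarray
    lam: float


@dataclass(frozen=True)
class ProjectedRates:
    values: np.ndarray  # (n_trials, n_bins)
    times: np.ndarray  # bin centers, seconds from the alignment event
    bin_s: float
    smoothing_s: float
    alignment: str  # "stimulus" | "saccade"


@dataclass(frozen=True)
class CPTimeSeries:
    times: np.ndarray
    cp: np.ndarray  # NaN where one choice class is empty
    axis: str  # "stimulus" | "choice"
    alignment: str
    readout: str = "fixed"
    smoothed: bool = False


def count_trial_spikes(
    bundle: SessionBundle,
    window: tuple[float, float] = COUNT_WINDOW_S,
) -> np.ndarray:
    """Per-trial, per-unit spike counts in the half-open window [start, end)."""
    n_trials, n_units = bundle.n_trials, bundle.n_units
    counts = np.zeros((n_trials, n_units), dtype=int)
    spk = bundle.spikes
    in_win = (spk["time_s"] >= window[0]) & (spk["time_s"] < window[1])
    for (t, u), c in spk[in_win].groupby(["trial_id", "unit_id"]).size().items():
        counts[int(t), int(u)] = c
    return counts


def fit_decoder(
    counts: np.ndarray,
    labels: np.ndarray,
    target: str,
    trials_filter: np.ndarray | None = None,
    lam: float = 1e-4,
    count_window: tuple[float, float] = COUNT_WINDOW_S,
) -> DecoderModel:
    """Logistic-regression decoder from trial spike counts to a binary label.

    Counts are standardized per unit before fitting; the small ridge
    ``lam`` (on the standardized scale) stabilizes the fit when the
    training set is separable or small relative to the population size.
    The returned weights are mapped back to the raw-count scale so they
    can be applied directly to binned rates.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if trials_filter is None:
        trials_filter = np.arange(len(counts))
    trials_filter = np.asarray(trials_filter)
    Xt, yt = counts[trials_filter], labels[trials_filter].astype(float)
    if len(np.unique(yt)) < 2:
        raise ValueError("training labels contain a single class")
    if len(Xt) < Xt.shape[1]:
        import warnings

        warnings.warn(
            f"{len(Xt)} training trials for {Xt.shape[1]} units: "
            "the decoder is ill-posed and relies on the ridge penalty",
            stacklevel=2,
        )
    mean = Xt.mean(axis=0)
    scale = Xt.std(axis=0)
    dead = scale == 0
    scale[dead] = 1.0
    w_std, b = ridge_logistic((Xt - mean) / scale, yt, lam)
    w_raw = w_std / scale
    w_raw[dead] = 0.0
    return DecoderModel(
        weights=w_raw,
        intercept=float(b - np.sum(w_std * mean / scale)),
        target=target,
        count_window=count_window,
        training_trials=trials_filter,
        lam=lam,
    )


def fit_direction_decoder(bundle: SessionBundle, lam: float = 1e-4) -> DecoderModel:
    """Direction decoder: all non-frozen trials with a nonzero pulse sum."""
    counts = count_trial_spikes(bundle)
    net = bundle.pulse_matrix().sum(axis=1)
    keep = np.flatnonzero((bundle.trials["frozen"].to_numpy() == 0) & (net != 0))
    labels = (net > 0).astype(int)
    return fit_decoder(counts, labels, "direction", keep, lam=lam)


def fit_choice_decoder_counts(bundle: SessionBundle, lam: float = 1e-4) -> DecoderModel:
    """Choice decoder: zero-sum frozen-noise trials only."""
    counts = count_trial_spikes(bundle)
    keep = np.flatnonzero(bundle.trials["frozen"].to_numpy() == 1)
    labels = bundle.trials["choice"].to_numpy()
    return fit_decoder(counts, labels, "choice", keep, lam=lam)


def binned_rates(
    bundle: SessionBundle,
    window: tuple[float, float],
    bin_s: float = 0.010,
    alignment: str = "stimulus",
) -> tuple[np.ndarray, np.ndarray]:
    """(n_trials, n_units, n_bins) spike rates on a uniform grid.

    ``alignment="stimulus"`` bins relative to stimulus onset,
    ``"saccade"`` relative to each trial's saccade time.
    """
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + np.arange(n_bins + 1) * bin_s
    rates = np.zeros((bundle.n_trials, bundle.n_units, n_bins))
    if alignment == "stimulus":
        offsets = np.zeros(bundle.n_trials)
    elif alignment == "saccade":
        offsets = bundle.trials["t_sacc"].to_numpy()
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    for (t, u), times in bundle.spikes.groupby(["trial_id", "unit_id"])["time_s"]:
        hist, _ = np.histogram(times.to_numpy() - offsets[int(t)], bins=edges)
        rates[int(t), int(u)] = hist / bin_s
    centers = edges[:-1] + bin_s / 2.0
    return rates, centers


def project_rates(
    model: DecoderModel,
    bundle: SessionBundle,
    window: tuple[float, float] = COUNT_WINDOW_S,
    bin_s: float = 0.010,
    smooth_s: float = 0.050,
    alignment: str = "stimulus",
) -> ProjectedRates:
    """Apply decoder weights to binned, boxcar-smoothed single-trial rates.

    The intercept is excluded: it shifts both choice-conditioned
    distributions equally and cannot affect the ROC.
    """
    rates, centers = binned_rates(bundle, window, bin_s=bin_s, alignment=alignment)
    width = max(int(round(smooth_s / bin_s)), 1)
    smoothed = boxcar_smooth(rates, width, axis=-1)
    values = np.einsum("tub,u->tb", smoothed, model.weights)
    return ProjectedRates(
        values=values,
        times=centers,
        bin_s=bin_s,
        smoothing_s=smooth_s,
        alignment=alignment,
    )


def roc_auc(group0: np.ndarray, group1: np.ndarray) -> float:
    """Area under the ROC curve separating two samples.

    Equals the Mann-Whitney U statistic divided by ``n0 * n1``, counting
    ties as 1/2: the probability that a random draw from ``group1``
    exceeds one from ``group0``.
    """
    group0 = np.asarray(group0, dtype=float)
    group1 = np.asarray(group1, dtype=float)
    if len(group0) == 0 or len(group1) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([group0, group1]))
    u1 = ranks[len(group0):].sum() - len(group1) * (len(group1) + 1) / 2.0
    return float(u1 / (len(group0) * len(group1)))


def cp_timecourse(
    proj: ProjectedRates,
    choices: np.ndarray,
    axis: str = "choice",
    smooth_s: float = 0.0,
) -> CPTimeSeries:
    """Choice probability per time bin from choice-conditioned projections.

    CP > 0.5 means a higher projection predicts choice = 1. Bins where
    one choice class is empty yield NaN. ``smooth_s > 0`` applies the
    conventional boxcar smoothing of the CP trace (display smoothing; the
    unsmoothed values are the estimator).
    """
    choices = np.asarray(choices).astype(int)
    g0, g1 = proj.values[choices == 0], proj.values[choices == 1]
    n_bins = proj.values.shape[1]
    cp = np.full(n_bins, np.nan)
    if len(g0) and len(g1):
        for b in range(n_bins):
            cp[b] = roc_auc(g0[:, b], g1[:, b])
    smoothed = smooth_s > 0
    if smoothed:
        width = max(int(round(smooth_s / proj.bin_s)), 1)
        valid = ~np.isnan(cp)
        if valid.all():
            cp = boxcar_smooth(cp, width)
    return CPTimeSeries(
        times=proj.times,
        cp=cp,
        axis=axis,
        alignment=proj.alignment,
        readout="fixed",
        smoothed=smoothed,
    )
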