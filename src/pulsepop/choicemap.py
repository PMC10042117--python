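"""Stimulus-residualized choice decoding and pooled choice probability.

Choice probability on latent factors must not be inflated by stimulus
information or by multidimensionality, so the analysis proceeds in
guarded steps:

1. *Weak-trial selection.* Only low-coherence trials on which the
   subject's accuracy stays below 65% enter the choice analyses: levels
   of |net pulse sum| are included in increasing order, starting at zero,
   until adding the next level would push pooled accuracy to the
   threshold. Sessions with fewer than 100 weak trials are excluded.
2. *Residualization.* Factors are rebinned at 100 ms and the per-bin
   linear pulse contribution is regressed out (ridge, strength by GCV);
   the residuals carry whatever is not explained by the stimulus.
3. *Choice decoding.* An L2-penalized logistic model predicts choice from
   window-summed residuals, with its penalty chosen by five-fold
   cross-validation (classes balanced in test folds, per session).
4. *Choice mapping.* ``c = sigmoid(beta . r + beta0)`` maps each trial's
   residual onto [0, 1], computed only on trials held out from the fold
   that trained the decoder, then pooled for a single ROC-based CP. The
   test-set-only mapping guarantees CP is not overestimated.

Fixed-readout CP fits the decoder once per epoch (stimulus period, or
the pre-saccadic delay) and applies it within each time bin; dynamic
readout refits per 100 ms bin. The RT median split probes whether the
delay-period choice signal is locked to the saccade or arises earlier on
slow trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._util import ridge_logistic, sigmoid
from .popdecode import CPTimeSeries, roc_auc
from .pta import gcv_select
from .synth import FactorSession

ACCURACY_THRESHOLD = 0.65
MIN_WEAK_TRIALS = 100
LAMBDA_GRID = np.logspace(-4, 2, 13)
N_FOLDS = 5


@dataclass(frozen=True)
class WeakTrialSet:
    trial_ids: np.ndarray
    coherence_levels_included: np.ndarray
    accuracy: float
    excluded: bool
    accuracy_threshold: float = ACCURACY_THRESHOLD
    min_trials: int = MIN_WEAK_TRIALS


@dataclass(frozen=True)
class ResidualFactors:
    residuals: np.ndarray  # (n_trials, n_bins, K)
    weights: np.ndarray  # (n_bins, 7, K)
    lambda_tilde: float
    bin_s: float
    times: np.ndarray


@dataclass(frozen=True)
class ChoiceDecoder:
    beta: np.ndarray
    beta0: float
    lambda_hat: float
    cv_folds: int
    mean: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class ChoiceMapValues:
    c: np.ndarray  # per-trial, in [0, 1], test-fold provenance only
    fold_id: np.ndarray


def select_weak_trials(
    net_coherence: np.ndarray,
    correct: np.ndarray,
    threshold: float = ACCURACY_THRESHOLD,
    min_trials: int = MIN_WEAK_TRIALS,
) -> WeakTrialSet:
    """Largest low-coherence prefix whose pooled accuracy stays below threshold.

    ``net_coherence`` is the per-trial |pulse sum| (zero for frozen and
    zero-sum trials); ``correct`` the per-trial reward outcome. Inclusion
    starts at zero coherence and adds levels in increasing magnitude; the
    first level whose addition lifts pooled accuracy to >= threshold stops
    the scan.
    """
    coh = np.abs(np.asarray(net_coherence, dtype=float))
    correct = np.asarray(correct, dtype=float)
    levels = np.unique(coh)
    included: list[float] = []
    mask = np.zeros(len(coh), dtype=bool)
    for level in levels:
        cand = mask | (coh == level)
        if included and correct[cand].mean() >= threshold:
            break
        mask = cand
        included.append(float(level))
    acc = float(correct[mask].mean()) if mask.any() else np.nan
    return WeakTrialSet(
        trial_ids=np.flatnonzero(mask),
        coherence_levels_included=np.array(included),
        accuracy=acc,
        excluded=int(mask.sum()) < min_trials,
        accuracy_threshold=threshold,
        min_trials=min_trials,
    )


def rebin_factors(
    factors: np.ndarray, bin_s: float, target_bin_s: float = 0.1
) -> np.ndarray:
    """Sum (n_trials, bins, K) factors into coarser bins; trailing partial
    bins are dropped."""
    ratio = int(round(target_bin_s / bin_s))
    n_out = factors.shape[1] // ratio
    trimmed = factors[:, : n_out * ratio]
    return trimmed.reshape(factors.shape[0], n_out, ratio, factors.shape[2]).sum(axis=2)


def residualize(
    factors: np.ndarray,
    pulse_values: np.ndarray,
    lambda_tilde: float | None = None,
    bin_s: float = 0.1,
    t0_s: float = 0.0,
) -> ResidualFactors:
    """Regress the pulses out of each 100 ms factor bin.

    Per bin ``t`` the model is ``x_t = sum_i w_ti * s_i + e`` across
    trials; the ridge strength is shared across bins and chosen by GCV on
    the stacked multi-output problem. Both sides are centered, so with an
    all-zero pulse matrix the residuals reduce to the centered factors.
    """
    X = np.asarray(factors, dtype=float)
    S = np.asarray(pulse_values, dtype=float)
    n, n_bins, K = X.shape
    S_c = S - S.mean(axis=0)
    X_mean = X.mean(axis=0)
    X_c = (X - X_mean).reshape(n, n_bins * K)
    if not np.any(S_c):
        residuals = X - X_mean
        weights = np.zeros((n_bins, S.shape[1], K))
        lam = 0.0 if lambda_tilde is None else lambda_tilde
    else:
        if lambda_tilde is None:
            lambda_tilde, _ = gcv_select(S_c, X_c, np.logspace(-2, 4, 17))
        lam = float(lambda_tilde)
        G = S_c.T @ S_c + lam * np.eye(S.shape[1])
        W = np.linalg.solve(G, S_c.T @ X_c)  # (7, bins*K)
        residuals = (X_c - S_c @ W).reshape(n, n_bins, K)
        weights = W.reshape(S.shape[1], n_bins, K).transpose(1, 0, 2)
    times = t0_s + (np.arange(n_bins) + 0.5) * bin_s
    return ResidualFactors(
        residuals=residuals, weights=weights, lambda_tilde=lam,
        bin_s=bin_s, times=times,
    )


# ---------------------------------------------------------------------------
# cross-validated choice decoding and mapping
# ---------------------------------------------------------------------------

def _cv_loglik(X: np.ndarray, y: np.ndarray, lam: float, folds) -> float:
    total = 0.0
    for train, test in folds:
        mean, scale = X[train].mean(0), X[train].std(0)
        scale[scale == 0] = 1.0
        w, b = ridge_logistic((X[train] - mean) / scale, y[train], lam)
        z = ((X[test] - mean) / scale) @ w + b
        total += float(np.sum(y[test] * z - np.logaddexp(0.0, z)))
    return total


def fit_choice_decoder(
    residual_sum: np.ndarray,
    choices: np.ndarray,
    lam_grid: np.ndarray = LAMBDA_GRID,
    n_folds: int = N_FOLDS,
    seed: int = 0,
) -> tuple[ChoiceDecoder, ChoiceMapValues]:
    """Regularized logistic choice decoder with out-of-fold choice mapping.

    ``residual_sum`` is (n_trials, K), the residual factors summed over
    the analysis window. The penalty is selected by stratified five-fold
    cross-validated log-likelihood; the returned mapping values ``c`` are
    produced exclusively by decoders that never saw their trial.
    """
    X = np.asarray(residual_sum, dtype=float)
    y = np.asarray(choices).astype(int)
    if n_folds != N_FOLDS:
        raise ValueError("the cross-validation protocol is fixed at 5 folds")
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("choices contain a single class")
    if class_counts.min() < n_folds:
        raise ValueError(
            f"minority class has {class_counts.min()} trials; "
            f"cannot balance {n_folds} test folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    scores = [_cv_loglik(X, y, lam, folds) for lam in lam_grid]
    lam_hat = float(lam_grid[int(np.argmax(scores))])

    c = np.full(len(y), np.nan)
    fold_id = np.full(len(y), -1)
    for f, (train, test) in enumerate(folds):
        mean, scale = X[train].mean(0), X[train].std(0)
        scale[scale == 0] = 1.0
        w, b = ridge_logistic((X[train] - mean) / scale, y[train], lam_hat)
        c[test] = sigmoid(((X[test] - mean) / scale) @ w + b)
        fold_id[test] = f
    mean, scale = X.mean(0), X.std(0)
    scale[scale == 0] = 1.0
    w_all, b_all = ridge_logistic((X - mean) / scale, y, lam_hat)
    decoder = ChoiceDecoder(
        beta=w_all / scale, beta0=float(b_all - np.sum(w_all * mean / scale)),
        lambda_hat=lam_hat, cv_folds=n_folds, mean=mean, scale=scale,
    )
    return decoder, ChoiceMapValues(c=c, fold_id=fold_id)


def choice_mapping(decoder: ChoiceDecoder, residual_sum: np.ndarray) -> np.ndarray:
    """Apply a fitted decoder's sigmoid mapping to residuals it was not
    trained on (leakage control is the caller's responsibility when using
    this directly; prefer the out-of-fold values from
    :func:`fit_choice_decoder`)."""
    X = np.asarray(residual_sum, dtype=float)
    return sigmoid(X @ decoder.beta + decoder.beta0)


def pooled_cp(
    c: np.ndarray, choices: np.ndarray, fold_id: np.ndarray | None = None
) -> float:
    """ROC area between choice-conditioned mapping values.

    With ``fold_id`` given, the AUC is computed within each
    cross-validation fold and averaged weighted by the fold's number of
    choice pairs. Pooling scores across folds before a single ROC is
    pessimistically biased (each fold's decoder shifts its test scores
    jointly, and cross-fold score comparisons are incoherent); the
    fold-stratified average is unbiased at 0.5 under the null.
    """
    c = np.asarray(c, dtype=float)
    y = np.asarray(choices).astype(int)
    if fold_id is None:
        return roc_auc(c[y == 0], c[y == 1])
    fold_id = np.asarray(fold_id)
    total, weight = 0.0, 0.0
    for f in np.unique(fold_id):
        m = fold_id == f
        g0, g1 = c[m & (y == 0)], c[m & (y == 1)]
        if len(g0) and len(g1):
            total += len(g0) * len(g1) * roc_auc(g0, g1)
            weight += len(g0) * len(g1)
    if weight == 0:
        raise ValueError("no fold contains both choice classes")
    return total / weight


def _axis_columns(K: int, axis: str) -> np.ndarray:
    if axis == "all":
        return np.arange(K)
    if axis == "stimulus":
        return np.array([0])
    if axis == "nonstimulus":
        if K < 2:
            raise ValueError("nonstimulus axis needs K >= 2")
        return np.arange(1, K)
    raise ValueError(f"unknown axis {axis!r}")


def cp_fixed_readout(
    residuals: ResidualFactors,
    choices: np.ndarray,
    epoch_bins: np.ndarray | slice | None = None,
    axis: str = "all",
    alignment: str = "stimulus",
    seed: int = 0,
    smooth_s: float = 0.0,
) -> CPTimeSeries:
    """CP time course with decoder weights fitted once on an epoch.

    The decoder is trained (with the five-fold protocol) on residuals
    summed over ``epoch_bins``; the per-fold weights are then applied to
    each individual time bin of the held-out trials, and CP is computed
    per bin on the pooled out-of-fold mapping values.
    """
    R = residuals.residuals
    cols = _axis_columns(R.shape[2], axis)
    R = R[:, :, cols]
    y = np.asarray(choices).astype(int)
    if epoch_bins is None:
        epoch_bins = slice(None)
    X_epoch = R[:, epoch_bins].sum(axis=1)
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    folds = list(skf.split(X_epoch, y))
    scores = [_cv_loglik(X_epoch, y, lam, folds) for lam in LAMBDA_GRID]
    lam_hat = float(LAMBDA_GRID[int(np.argmax(scores))])
    n_bins = R.shape[1]
    c_bins = np.full((len(y), n_bins), np.nan)
    fold_id = np.full(len(y), -1)
    for f, (train, test) in enumerate(folds):
        mean, scale = X_epoch[train].mean(0), X_epoch[train].std(0)
        scale[scale == 0] = 1.0
        w, b = ridge_logistic((X_epoch[train] - mean) / scale, y[train], lam_hat)
        w_raw = w / scale
        fold_id[test] = f
        for t in range(n_bins):
            c_bins[test, t] = sigmoid(R[test, t] @ w_raw + b)
    cp = np.full(n_bins, np.nan)
    for t in range(n_bins):
        try:
            cp[t] = pooled_cp(c_bins[:, t], y, fold_id)
        except ValueError:
            pass
    if smooth_s > 0:
        from ._util import boxcar_smooth

        width = max(int(round(smooth_s / residuals.bin_s)), 1)
        cp = boxcar_smooth(cp, width)
    return CPTimeSeries(
        times=residuals.times, cp=cp, axis=axis, alignment=alignment,
        readout="fixed", smoothed=smooth_s > 0,
    )


def cp_dynamic_readout(
    residuals: ResidualFactors,
    choices: np.ndarray,
    axis: str = "all",
    alignment: str = "stimulus",
    seed: int = 0,
) -> CPTimeSeries:
    """CP time course with the decoder refit independently per 100 ms bin."""
    R = residuals.residuals
    cols = _axis_columns(R.shape[2], axis)
    R = R[:, :, cols]
    y = np.asarray(choices).astype(int)
    n_bins = R.shape[1]
    cp = np.full(n_bins, np.nan)
    for t in range(n_bins):
        try:
            _, mapping = fit_choice_decoder(R[:, t], y, seed=seed)
            cp[t] = pooled_cp(mapping.c, y, mapping.fold_id)
        except ValueError:
            cp[t] = np.nan
    return CPTimeSeries(
        times=residuals.times, cp=cp, axis=axis, alignment=alignment,
        readout="dynamic", smoothed=False,
    )


def cp_by_rt_split(
    residuals: ResidualFactors,
    choices: np.ndarray,
    rt_s: np.ndarray,
    epoch_bins: np.ndarray | slice | None = None,
    axis: str = "all",
    alignment: str = "saccade",
    seed: int = 0,
) -> tuple[CPTimeSeries, CPTimeSeries]:
    """Fixed-readout CP computed separately for short- and long-RT halves.

    Trials at exactly the median RT go to the short (lower) half. Returns
    (short_rt_series, long_rt_series).
    """
    rt_s = np.asarray(rt_s, dtype=float)
    y = np.asarray(choices).astype(int)
    median = np.median(rt_s)
    long_mask = rt_s > median
    out = []
    for mask in (~long_mask, long_mask):
        if mask.sum() < 2 * N_FOLDS:
            raise ValueError("too few trials in an RT half for 5-fold CV")
        sub = ResidualFactors(
            residuals=residuals.residuals[mask],
            weights=residuals.weights,
            lambda_tilde=residuals.lambda_tilde,
            bin_s=residuals.bin_s,
            times=residuals.times,
        )
        out.append(
            cp_fixed_readout(
                sub, y[mask], epoch_bins=epoch_bins, axis=axis,
                alignment=alignment, seed=seed,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# alignment helpers for factor sessions
# ---------------------------------------------------------------------------

def saccade_aligned_factors(
    fs: FactorSession, window: tuple[float, float] = (-0.5, 0.0)
) -> np.ndarray:
    """Extract per-trial factor bins in a window relative to the saccade.

    Bins are taken from the session's stimulus-aligned grid at the indices
    nearest each trial's saccade-relative window; all trials contribute
    the same number of bins.
    """
    n_bins = int(round((window[1] - window[0]) / fs.bin_s))
    out = np.zeros((len(fs.choices), n_bins, fs.factors.shape[2]))
    for i, t_sacc in enumerate(fs.t_sacc):
        start = int(round((t_sacc + window[0] - fs.t0_s) / fs.bin_s))
        start = max(0, min(start, fs.factors.shape[1] - n_bins))
        out[i] = fs.factors[i, start : start + n_bins]
    return out
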