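"""Pulse-triggered average (PTA) via cosine-basis ridge regression.

The PTA measures the change in a one- or multi-dimensional population
response (the decoder projection, or latent factors) caused by one extra
signal element of motion at each of the seven pulse positions. Each
pulse's influence is expanded on four raised-cosine temporal bases
(starting 0, 50, 100 and 150 ms after pulse onset, 100 ms support each,
so 28 regressors in total), scaled by the pulse strength, and the basis
weights are estimated by ridge regression over all trials concatenated in
time, with the ridge strength chosen by generalized cross-validation
(GCV). The reconstructed unit-strength response curves are smoothed with
a temporal Gaussian and peak-normalized per session; the seven per-pulse
peaks summarize the time-varying stimulus gain, and an exponential decay
``a * exp(b * i)`` is the conventional model of their falloff over pulse
index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._util import gaussian_smooth
from .stimgen import N_PULSES

PULSE_DUR_MS = 150
BASIS_STARTS_MS = (0, 50, 100, 150)
BASIS_DUR_MS = 100
N_BASES = len(BASIS_STARTS_MS)
PTA_SPAN_MS = BASIS_STARTS_MS[-1] + BASIS_DUR_MS  # 250 ms per pulse

#: smoothing of the reconstructed curves: a 40 ms-wide temporal Gaussian,
#: width read as full width at half maximum (sigma = 40 / 2.355)
GAUSS_SIGMA_MS = 40.0 / 2.355


@dataclass(frozen=True)
class PtaDesign:
    D: np.ndarray  # (T, 28)
    n_trials: int
    trial_len_ms: int
    resolution_ms: int

    @property
    def bins_per_trial(self) -> int:
        return self.trial_len_ms // self.resolution_ms


@dataclass(frozen=True)
class PtaResult:
    W: np.ndarray  # (28, K) basis weights
    curves: np.ndarray  # (7, span_bins, K), smoothed, unnormalized
    normalized_curves: np.ndarray  # peak-normalized per dimension
    peaks: np.ndarray  # (7, K) per-pulse peak magnitudes (smoothed curves)
    lambda_prime: float
    resolution_ms: int


@dataclass(frozen=True)
class ExpFit:
    a: float
    b: float
    r_squared: float
    converged: bool


def _raised_cosine(n_bins: int) -> np.ndarray:
    """Raised-cosine bump (1 - cos(2*pi*u)) / 2 over its support."""
    u = (np.arange(n_bins) + 0.5) / n_bins
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def basis_matrix(trial_len_ms: int, resolution_ms: int = 1) -> np.ndarray:
    """(bins_per_trial, 28) unit-strength basis functions for one trial."""
    bins = trial_len_ms // resolution_ms
    B = np.zeros((bins, N_PULSES * N_BASES))
    dur_bins = BASIS_DUR_MS // resolution_ms
    bump = _raised_cosine(dur_bins)
    for i in range(N_PULSES):
        onset = i * PULSE_DUR_MS
        for j, start in enumerate(BASIS_STARTS_MS):
            b0 = (onset + start) // resolution_ms
            b1 = min(b0 + dur_bins, bins)
            B[b0:b1, N_BASES * i + j] = bump[: b1 - b0]
    return B


def build_design(
    pulse_values: np.ndarray,
    trial_len_ms: int = 1200,
    resolution_ms: int = 1,
) -> PtaDesign:
    """Stack the per-trial basis matrices, scaled by each trial's pulses.

    Trials are concatenated along time; within each trial, the four bases
    of pulse ``i`` occupy columns ``4*i .. 4*i+3`` and are multiplied by
    that trial's pulse strength ``s_i`` (zero pulses contribute nothing).
    """
    pulse_values = np.asarray(pulse_values, dtype=float)
    if pulse_values.ndim != 2 or pulse_values.shape[1] != N_PULSES:
        raise ValueError("pulse_values must be (n_trials, 7)")
    B = basis_matrix(trial_len_ms, resolution_ms)
    scale = np.repeat(pulse_values, N_BASES, axis=1)  # (n_trials, 28)
    D = (scale[:, None, :] * B[None, :, :]).reshape(-1, N_PULSES * N_BASES)
    return PtaDesign(
        D=D,
        n_trials=len(pulse_values),
        trial_len_ms=trial_len_ms,
        resolution_ms=resolution_ms,
    )


def upsample_response(
    values: np.ndarray,
    bin_ms: int,
    trial_len_ms: int,
    resolution_ms: int = 1,
    center: bool = True,
) -> np.ndarray:
    """Repeat binned responses onto the design's time grid, then stack trials.

    ``values`` is (n_trials, n_bins) or (n_trials, n_bins, K); returns
    (n_trials * bins_per_trial, K). With ``center=True`` the across-trial
    mean time course (the stimulus-independent PSTH) is subtracted per
    bin first; pulse strengths average to ~0 across trials, so this does
    not bias the PTA but removes a large common component from the
    regression residual.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    if center:
        values = values - values.mean(axis=0, keepdims=True)
    rep = bin_ms // resolution_ms
    out_bins = trial_len_ms // resolution_ms
    up = np.repeat(values, rep, axis=1)[:, :out_bins, :]
    if up.shape[1] < out_bins:
        raise ValueError("response does not cover the design's trial length")
    return up.reshape(-1, values.shape[2])


def gcv_select(
    D: np.ndarray,
    X: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Ridge strength minimizing the generalized cross-validation score.

    ``GCV(lam) = ||(I - H_lam) X||^2 / (T * (1 - tr(H_lam)/T))^2`` with
    ``H_lam`` the ridge hat matrix; multi-column ``X`` sums squared
    residuals over columns. Returns the winning ``lam`` and a diagnostics
    dict (the score curve and an edge flag).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != D.shape[0]:
        X = X.T
    if grid is None:
        grid = np.logspace(-2, 6, 25)
    grid = np.asarray(grid, dtype=float)
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    C = U.T @ X  # (rank, K)
    T = D.shape[0]
    sum_sq = np.sum(X**2)
    scores = np.empty(len(grid))
    for i, lam in enumerate(grid):
        f = s**2 / (s**2 + lam)
        rss = sum_sq - np.sum((2.0 * f - f**2)[:, None] * C**2)
        scores[i] = rss / (T * (1.0 - np.sum(f) / T)) ** 2
    best = int(np.argmin(scores))
    info = {
        "grid": grid,
        "scores": scores,
        "at_edge": best in (0, len(grid) - 1) and len(grid) > 1,
    }
    return float(grid[best]), info


def _ridge_solve(D: np.ndarray, X: np.ndarray, lam: float) -> np.ndarray:
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    shrink = s / (s**2 + lam)
    return Vt.T @ (shrink[:, None] * (U.T @ X))


def fit_pta(
    response: np.ndarray,
    design: PtaDesign,
    lambda_prime: float | None = None,
    gcv_grid: np.ndarray | None = None,
    gauss_sigma_ms: float = GAUSS_SIGMA_MS,
) -> PtaResult:
    """Estimate the PTA from a concatenated response and its pulse design.

    ``response`` is (T,) or (T, K) on the design's time grid. The ridge
    weights are reconstructed into seven unit-strength response curves
    (one per pulse position, [0, 250) ms after pulse onset), smoothed with
    a temporal Gaussian (sigma ``gauss_sigma_ms``), and normalized by the
    per-dimension peak magnitude. Each dimension's overall sign is chosen
    so its largest-magnitude response is positive.
    """
    X = np.asarray(response, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != design.D.shape[0]:
        raise ValueError("response and design must share the time axis")
    if not np.any(design.D):
        raise ValueError("all-zero design: no pulses to regress on")
    if lambda_prime is None:
        lambda_prime, _ = gcv_select(design.D, X, gcv_grid)
    if lambda_prime < 0:
        raise ValueError("lambda_prime must be non-negative")
    W = _ridge_solve(design.D, X, lambda_prime)  # (28, K)

    span = PTA_SPAN_MS // design.resolution_ms
    dur = BASIS_DUR_MS // design.resolution_ms
    bump = _raised_cosine(dur)
    K = X.shape[1]
    curves = np.zeros((N_PULSES, span, K))
    for i in range(N_PULSES):
        for j, start in enumerate(BASIS_STARTS_MS):
            b0 = start // design.resolution_ms
            curves[i, b0 : b0 + dur] += bump[:, None] * W[N_BASES * i + j]
    sigma_bins = gauss_sigma_ms / design.resolution_ms
    curves = gaussian_smooth(curves, sigma_bins, axis=1)
    # orient each dimension so its dominant response is positive
    for k in range(K):
        flat = curves[:, :, k]
        if flat[np.unravel_index(np.argmax(np.abs(flat)), flat.shape)] < 0:
            curves[:, :, k] *= -1.0
    peaks = curves.max(axis=1)  # (7, K)
    peak_mag = np.abs(curves).reshape(-1, K).max(axis=0)
    peak_mag[peak_mag == 0] = 1.0
    normalized = curves / peak_mag[None, None, :]
    return PtaResult(
        W=W,
        curves=curves,
        normalized_curves=normalized,
        peaks=peaks,
        lambda_prime=float(lambda_prime),
        resolution_ms=design.resolution_ms,
    )


def fit_exponential(per_pulse_peaks: np.ndarray) -> ExpFit:
    """Nonlinear least-squares fit of ``a * exp(b * i)`` to the 7 peaks.

    Falls back to the log-linear fit when the nonlinear optimizer fails
    (possible only for pathological peak patterns).
    """
    peaks = np.asarray(per_pulse_peaks, dtype=float)
    if peaks.shape != (N_PULSES,):
        raise ValueError("expected 7 per-pulse peaks")
    idx = np.arange(1, N_PULSES + 1, dtype=float)
    if np.all(peaks > 0):
        b0, loga0 = np.polyfit(idx, np.log(peaks), 1)
        p0 = (float(np.exp(loga0)), float(b0))
    else:
        p0 = (max(peaks.mean(), 1e-3), 0.0)
    converged = True
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x), idx, peaks, p0=p0, maxfev=10000
            )
        a, b = float(popt[0]), float(popt[1])
    except RuntimeError:
        a, b = p0
        converged = False
    fitted = a * np.exp(b * idx)
    ss_res = float(np.sum((peaks - fitted) ** 2))
    ss_tot = float(np.sum((peaks - peaks.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return ExpFit(a=a, b=b, r_squared=r2, converged=converged)
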