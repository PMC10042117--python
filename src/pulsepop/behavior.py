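"""Psychometric and temporal-weighting (psychophysical kernel) fits.

Two behavioral models are fit from trial tables:

* a three-parameter logistic psychometric function of net motion strength
  ``x``::

      p(choice = 1) = gamma + (1 - 2*gamma) / (1 + exp(-beta * (x - alpha)))

  with bias ``alpha`` (motion-strength units), sensitivity ``beta``
  (log-odds per unit motion strength) and lapse rate ``gamma``; and

* a 7-weight temporal kernel mapping per-pulse motion strengths to the
  binary choice by ridge-penalized logistic regression, with the ridge
  strength set by empirical-Bayes evidence optimization (Laplace
  approximation to the marginal likelihood). The kernel describes *when*
  within the trial the evidence influences the decision.

Both use all trials, including zero-mean and frozen-noise trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .stimgen import N_PULSES

_SIGMOID_CLIP = 30.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_SIGMOID_CLIP, _SIGMOID_CLIP)))


# ---------------------------------------------------------------------------
# psychometric function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    se_alpha: float
    se_beta: float
    se_gamma: float
    loglik: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        """P(choice = 1) at motion strength x."""
        return self.gamma + (1.0 - 2.0 * self.gamma) * _sigmoid(
            self.beta * (np.asarray(x, dtype=float) - self.alpha)
        )


def _psy_nll_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    alpha, beta, gamma = theta
    sig = _sigmoid(beta * (x - alpha))
    p = np.clip(gamma + (1.0 - 2.0 * gamma) * sig, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    resid = y / p - (1.0 - y) / (1.0 - p)
    dsig = (1.0 - 2.0 * gamma) * sig * (1.0 - sig)
    grad = -np.array(
        [
            np.sum(resid * dsig * (-beta)),
            np.sum(resid * dsig * (x - alpha)),
            np.sum(resid * (1.0 - 2.0 * sig)),
        ]
    )
    return nll, grad


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    d = len(theta)
    hess = np.zeros((d, d))
    for j in range(d):
        step = np.zeros(d)
        step[j] = eps * max(1.0, abs(theta[j]))
        _, gp = fun(theta + step)
        _, gm = fun(theta - step)
        hess[:, j] = (gp - gm) / (2.0 * step[j])
    return 0.5 * (hess + hess.T)


def fit_psychometric(
    x: np.ndarray,
    choices: np.ndarray,
    gamma_max: float = 0.25,
    n_starts: int = 3,
    seed: int = 0,
) -> PsychometricFit:
    """Maximum-likelihood fit of the three-parameter logistic.

    ``x`` is the per-trial net motion strength (z-scoring, if desired, is
    the caller's responsibility). Standard errors come from the square root
    of the diagonal of the inverse Hessian of the negative log-likelihood
    at the MLE. The lapse is bounded in ``[0, gamma_max]`` for stability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(choices, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct motion-strength values")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate input: all choices identical")
    fun = lambda th: _psy_nll_grad(th, x, y)
    bounds = [(None, None), (None, None), (0.0, gamma_max)]
    rng = np.random.default_rng(seed)
    scale = np.std(x) or 1.0
    starts = [np.array([0.0, 1.0 / scale, 0.02])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.normal(0.0, 0.5 * scale),
                    np.exp(rng.normal(0.0, 1.0)) / scale,
                    rng.uniform(0.0, gamma_max / 2),
                ]
            )
        )
    best = None
    for start in starts:
        res = optimize.minimize(fun, start, jac=True, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    hess = _numeric_hessian(fun, best.x)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return PsychometricFit(
        alpha=float(best.x[0]),
        beta=float(best.x[1]),
        gamma=float(best.x[2]),
        se_alpha=float(se[0]),
        se_beta=float(se[1]),
        se_gamma=float(se[2]),
        loglik=float(-best.fun),
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# temporal kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalKernel:
    weights: np.ndarray  # 7 raw log-odds weights per signal element
    bias: float
    lambda_ridge: float
    normalized_weights: np.ndarray  # unit Euclidean norm
    slope_linear_fit: float
    loglik: float


def _kernel_nll_grad(wb: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float):
    """Penalized Bernoulli NLL; ridge on the 7 pulse weights, not the bias."""
    z = X @ wb
    p = _sigmoid(z)
    nll = -np.sum(y * z - np.logaddexp(0.0, z)) + lam * np.sum(wb[:N_PULSES] ** 2)
    grad = X.T @ (p - y)
    grad[:N_PULSES] += 2.0 * lam * wb[:N_PULSES]
    return nll, grad


def _kernel_map(X: np.ndarray, y: np.ndarray, lam: float, w0=None) -> np.ndarray:
    w0 = np.zeros(X.shape[1]) if w0 is None else w0
    res = optimize.minimize(
        _kernel_nll_grad, w0, args=(X, y, lam), jac=True, method="L-BFGS-B"
    )
    return res.x


def _log_evidence(X: np.ndarray, y: np.ndarray, lam: float, w_map: np.ndarray) -> float:
    """Laplace approximation to log p(Y | lambda), up to a constant.

    The Gaussian prior on the 7 pulse weights has precision ``2 * lam``;
    the bias carries a flat prior and contributes only through the Hessian.
    """
    z = X @ w_map
    p = _sigmoid(z)
    loglik = float(np.sum(y * z - np.logaddexp(0.0, z)))
    hess = X.T @ (X * (p * (1.0 - p))[:, None])
    prior_prec = np.zeros(X.shape[1])
    prior_prec[:N_PULSES] = 2.0 * lam
    hess_post = hess + np.diag(prior_prec)
    sign, logdet = np.linalg.slogdet(hess_post)
    if sign <= 0:
        return -np.inf
    return (
        loglik
        - lam * np.sum(w_map[:N_PULSES] ** 2)
        + 0.5 * N_PULSES * np.log(2.0 * lam)
        - 0.5 * logdet
    )


def fit_temporal_kernel(
    pulse_values: np.ndarray,
    choices: np.ndarray,
    lambda_ridge: float | None = None,
    lam_grid: np.ndarray | None = None,
) -> TemporalKernel:
    """Ridge-penalized logistic regression of choice on the 7 pulse strengths.

    The design is the per-trial pulse strengths augmented by a column of
    ones for the bias. When ``lambda_ridge`` is not given it is chosen by
    evidence optimization: the Laplace-approximated marginal likelihood is
    maximized over a log-spaced grid with one stage of local refinement.
    The fitted weights are also reported normalized to unit Euclidean norm,
    together with the OLS slope of the normalized weights over pulse index
    (the standard summary of early- vs late-weighting).
    """
    P = np.asarray(pulse_values, dtype=float)
    y = np.asarray(choices, dtype=float)
    if P.ndim != 2 or P.shape[1] != N_PULSES:
        raise ValueError("pulse_values must be (n_trials, 7)")
    if len(y) != len(P):
        raise ValueError("choices and pulse_values must have equal length")
    X = np.column_stack([P, np.ones(len(P))])
    if np.linalg.matrix_rank(P) < N_PULSES:
        raise ValueError("singular pulse design: pulses are linearly dependent")

    if lambda_ridge is None:
        grid = lam_grid if lam_grid is not None else np.logspace(-3, 4, 25)
        w0 = None
        evidences = []
        for lam in grid:
            w0 = _kernel_map(X, y, lam, w0)
            evidences.append(_log_evidence(X, y, lam, w0))
        best = int(np.argmax(evidences))
        # local refinement around the grid optimum
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        fine = np.logspace(np.log10(lo), np.log10(hi), 9)
        fine_ev = [
            _log_evidence(X, y, lam, _kernel_map(X, y, lam)) for lam in fine
        ]
        lambda_ridge = float(fine[int(np.argmax(fine_ev))])
    if lambda_ridge <= 0:
        raise ValueError("lambda_ridge must be positive")

    wb = _kernel_map(X, y, lambda_ridge)
    weights, bias = wb[:N_PULSES], float(wb[N_PULSES])
    norm = np.linalg.norm(weights)
    normalized = weights / norm if norm > 0 else weights.copy()
    z = X @ wb
    loglik = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return TemporalKernel(
        weights=weights,
        bias=bias,
        lambda_ridge=float(lambda_ridge),
        normalized_weights=normalized,
        slope_linear_fit=kernel_slope_of(normalized),
        loglik=loglik,
    )


def kernel_slope_of(weights: np.ndarray) -> float:
    """OLS slope of weight versus pulse index (1..7)."""
    idx = np.arange(1, N_PULSES + 1, dtype=float)
    return float(np.polyfit(idx, np.asarray(weights, dtype=float), 1)[0])


def kernel_slope(kernel: TemporalKernel) -> float:
    """Slope of the linear fit to the normalized psychophysical kernel."""
    return kernel_slope_of(kernel.normalized_weights)


def kernel_permutation_band(
    pulse_values: np.ndarray,
    choices: np.ndarray,
    lambda_ridge: float,
    n_perm: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Null bands for kernel weights and slope from choice permutations.

    Choices are shuffled across trials (breaking any stimulus-choice
    relation) and the kernel refit at the given fixed ridge strength; the
    central ``level`` interval over permutations is returned for each
    normalized weight and for the kernel slope.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(choices, dtype=float)
    slopes = np.empty(n_perm)
    raw = np.empty((n_perm, N_PULSES))
    for i in range(n_perm):
        perm = rng.permutation(len(y))
        fit = fit_temporal_kernel(pulse_values, y[perm], lambda_ridge=lambda_ridge)
        slopes[i] = fit.slope_linear_fit
        raw[i] = fit.weights
    tail = (1.0 - level) / 2.0
    return {
        "slope_band": (
            float(np.quantile(slopes, tail)),
            float(np.quantile(slopes, 1.0 - tail)),
        ),
        "abs_slope_q": float(np.quantile(np.abs(slopes), level)),
        "abs_weight_q": np.quantile(np.abs(raw), level, axis=0),
        # family-wise band: null distribution of the largest |weight|
        "abs_max_weight_q": float(np.quantile(np.abs(raw).max(axis=1), level)),
        "weight_bands": np.quantile(raw, [tail, 1.0 - tail], axis=0),
    }
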