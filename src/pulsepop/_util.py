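"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy import optimize

_CLIP = 30.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_CLIP, _CLIP)))


def ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalize_intercept: bool = False,
) -> tuple[np.ndarray, float]:
    """MAP logistic regression: maximize loglik - lam * ||w||^2.

    An intercept column is appended internally; returns (weights, intercept).
    With ``lam = 0`` this is the plain (unpenalized) ML fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xa = np.column_stack([X, np.ones(len(X))])
    d = X.shape[1]
    mask = np.ones(d + 1)
    if not penalize_intercept:
        mask[-1] = 0.0

    def nll_grad(wb):
        z = Xa @ wb
        p = sigmoid(z)
        nll = -np.sum(y * z - np.logaddexp(0.0, z)) + lam * np.sum(mask * wb**2)
        grad = Xa.T @ (p - y) + 2.0 * lam * mask * wb
        return nll, grad

    res = optimize.minimize(
        nll_grad, np.zeros(d + 1), jac=True, method="L-BFGS-B",
        options={"maxiter": 500},
    )
    return res.x[:d], float(res.x[d])


def boxcar_smooth(values: np.ndarray, width_bins: int, axis: int = -1) -> np.ndarray:
    """Centered boxcar smoothing with edge truncation.

    Near the edges the window is truncated and renormalized by the number
    of in-window bins, so a constant input maps to itself exactly.
    """
    if width_bins <= 1:
        return np.asarray(values, dtype=float)
    values = np.asarray(values, dtype=float)
    kernel = np.ones(width_bins)
    ones = np.ones(values.shape[axis])
    norm = np.convolve(ones, kernel, mode="same")

    def smooth_1d(v):
        return np.convolve(v, kernel, mode="same") / norm

    return np.apply_along_axis(smooth_1d, axis, values)


def gaussian_smooth(values: np.ndarray, sigma_bins: float, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing with edge renormalization (constant-preserving)."""
    from scipy.ndimage import gaussian_filter1d

    values = np.asarray(values, dtype=float)
    num = gaussian_filter1d(values, sigma_bins, axis=axis, mode="constant")
    den = gaussian_filter1d(
        np.ones(values.shape[axis]), sigma_bins, mode="constant"
    )
    shape = [1] * values.ndim
    shape[axis] = -1
    return num / den.reshape(shape)
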