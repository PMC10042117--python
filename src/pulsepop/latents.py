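"""Latent Gaussian-process factors for population spike trains.

Spike counts binned at 10 ms are modeled as conditionally Poisson given a
low-dimensional smooth latent trajectory::

    y_t ~ Poisson(exp(A x_t + b)),      x_k ~ N(0, K_se)   per trial

where ``A`` (units x K) are the loadings, ``b`` the per-unit log
baselines, and each latent dimension carries an independent
squared-exponential GP prior over time within each trial. Inference uses
a variational approximation with per-trial, per-dimension Gaussian
posteriors ``q(x_k) = N(mu_k, Sigma_k)``; the posterior means are
analyzed as the latent factors. Fitting is coordinate-ascent variational
EM: damped Newton updates of the posterior means, fixed-point updates of
the posterior covariances (parameterized by their diagonal likelihood
precision, which keeps memory linear in trial length), and per-unit
Newton updates of the loadings and biases, each accepted only when it
does not decrease the evidence lower bound — so the ELBO is monotone
non-decreasing by construction.

Dimensionality is selected by leave-one-neuron-out cross-validation:
latents inferred from all other units predict the held-out unit's counts
through its fitted loading. The SVD rotation of the pulse-triggered-
average regression weights concentrates the stimulus-driven signal in the
first rotated factor (the "stimulus axis"), sorting factors by task
explanatory power.

GP hyperparameters (lengthscale, variance) are fixed, not learned; the
defaults (100 ms, unit variance) give trajectories smooth at the
timescale of the 150 ms pulses while the loading scale absorbs amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .synth import SessionBundle


@dataclass(frozen=True)
class LatentModel:
    loading: np.ndarray  # (n_units, K)
    bias: np.ndarray  # (n_units,)
    K: int
    gp_lengthscale_s: float
    gp_variance: float
    bin_s: float
    ridge: float


@dataclass
class LatentTrajectories:
    means: list[np.ndarray]  # per trial, (T_r, K)
    variances: list[np.ndarray]  # per trial, marginal posterior variances
    bin_s: float
    rotated: bool = False
    rotation: np.ndarray | None = None

    def stacked(self) -> np.ndarray:
        return np.concatenate(self.means, axis=0)


def se_covariance(n_bins: int, bin_s: float, lengthscale_s: float, variance: float,
                  jitter: float = 1e-6) -> np.ndarray:
    t = np.arange(n_bins) * bin_s
    d = t[:, None] - t[None, :]
    return variance * np.exp(-0.5 * (d / lengthscale_s) ** 2) + jitter * np.eye(n_bins)


class _PriorCache:
    """Per-trial-length cache of the GP prior inverse and log-determinant."""

    def __init__(self, bin_s: float, lengthscale_s: float, variance: float):
        self.bin_s = bin_s
        self.lengthscale_s = lengthscale_s
        self.variance = variance
        self._store: dict[int, tuple[np.ndarray, float]] = {}

    def get(self, n_bins: int) -> tuple[np.ndarray, float]:
        if n_bins not in self._store:
            Kmat = se_covariance(n_bins, self.bin_s, self.lengthscale_s, self.variance)
            cho = linalg.cho_factor(Kmat, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            Kinv = linalg.cho_solve(cho, np.eye(n_bins))
            self._store[n_bins] = (Kinv, logdet)
        return self._store[n_bins]


def bin_session_counts(
    bundle: SessionBundle,
    bin_s: float = 0.010,
    window: str = "targets_to_reward",
) -> list[np.ndarray]:
    """Per-trial (T_r, n_units) spike-count arrays on a 10 ms grid.

    ``window`` is ``"targets_to_reward"`` (the fit window of the latent
    model) or ``"stimulus"`` ([0, 1.2) s from stimulus onset).
    """
    tr = bundle.trials
    if window == "targets_to_reward":
        t0 = tr["t_targets_on"].to_numpy()
        t1 = tr["t_reward"].to_numpy()
    elif window == "stimulus":
        t0 = np.zeros(bundle.n_trials)
        t1 = np.full(bundle.n_trials, 1.2)
    else:
        raise ValueError(f"unknown window {window!r}")
    counts: list[np.ndarray] = []
    spikes_by_trial = dict(tuple(bundle.spikes.groupby("trial_id")))
    for r in range(bundle.n_trials):
        n_bins = int(np.floor((t1[r] - t0[r]) / bin_s))
        edges = t0[r] + np.arange(n_bins + 1) * bin_s
        mat = np.zeros((n_bins, bundle.n_units))
        if r in spikes_by_trial:
            sub = spikes_by_trial[r]
            for u, times in sub.groupby("unit_id")["time_s"]:
                mat[:, int(u)], _ = np.histogram(times.to_numpy(), bins=edges)
        counts.append(mat)
    return counts


# ---------------------------------------------------------------------------
# variational EM
# ---------------------------------------------------------------------------

class _VarState:
    """Posterior state for one fit: means and covariance precisions."""

    def __init__(self, counts: list[np.ndarray], K: int, prior: _PriorCache):
        self.prior = prior
        self.mu = [np.zeros((y.shape[0], K)) for y in counts]
        # w parameterizes Sigma_k = (Kinv + diag(w_k))^{-1}; w = 0 -> prior
        self.w = [np.zeros((y.shape[0], K)) for y in counts]
        self.sdiag = [
            np.full((y.shape[0], K), prior.variance) for y in counts
        ]
        self.kl = [np.zeros(K) for _ in counts]

    def refresh_trial_dim(self, r: int, k: int) -> None:
        """Recompute Sigma diag and KL for trial r, dim k from (mu, w)."""
        T = self.mu[r].shape[0]
        Kinv, logdetK = self.prior.get(T)
        prec = Kinv + np.diag(self.w[r][:, k])
        cho = linalg.cho_factor(prec, lower=True)
        logdet_prec = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Sigma = linalg.cho_solve(cho, np.eye(T))
        sd = np.diag(Sigma).copy()
        self.sdiag[r][:, k] = sd
        mu = self.mu[r][:, k]
        self.kl[r][k] = 0.5 * (
            mu @ Kinv @ mu - np.sum(self.w[r][:, k] * sd) + logdetK + logdet_prec
        )


def _trial_loglik(y: np.ndarray, mu: np.ndarray, sdiag: np.ndarray,
                  A: np.ndarray, b: np.ndarray) -> float:
    eta = mu @ A.T + b
    rho = np.exp(np.clip(eta + 0.5 * sdiag @ (A.T**2), -50, 50))
    return float(np.sum(y * eta - rho))


def _elbo(counts, state: _VarState, A, b, ridge) -> float:
    total = -ridge * float(np.sum(A**2))
    for r, y in enumerate(counts):
        total += _trial_loglik(y, state.mu[r], state.sdiag[r], A, b)
        total -= float(np.sum(state.kl[r]))
    return total


def _update_mu(y, mu, sdiag, A, b, k, Kinv, max_newton=4) -> np.ndarray:
    """Damped Newton ascent of the trial ELBO in mu[:, k] (concave)."""
    a_k = A[:, k]
    corr = 0.5 * sdiag @ (A.T**2)

    def obj(mk):
        m = mu.copy()
        m[:, k] = mk
        eta = m @ A.T + b
        rho = np.exp(np.clip(eta + corr, -50, 50))
        return float(np.sum(y * eta - rho)) - 0.5 * mk @ Kinv @ mk

    mk = mu[:, k].copy()
    f0 = obj(mk)
    for _ in range(max_newton):
        m = mu.copy()
        m[:, k] = mk
        eta = m @ A.T + b
        rho = np.exp(np.clip(eta + corr, -50, 50))
        grad = (y - rho) @ a_k - Kinv @ mk
        wdiag = rho @ (a_k**2)
        step = linalg.solve(Kinv + np.diag(wdiag), grad, assume_a="pos")
        alpha = 1.0
        improved = False
        for _ in range(8):
            cand = mk + alpha * step
            f1 = obj(cand)
            if f1 >= f0:
                mk, f0, improved = cand, f1, True
                break
            alpha *= 0.5
        if not improved:
            break
    return mk


def _update_unit(y_col, Mu, Sd, a, b0, ridge, max_newton=4):
    """Newton ascent of the ELBO in one unit's loading row and bias."""
    K = Mu.shape[1]

    def obj(ab):
        a_, b_ = ab[:K], ab[K]
        eta = Mu @ a_ + b_ + 0.5 * Sd @ (a_**2)
        rho = np.exp(np.clip(eta, -50, 50))
        lin = Mu @ a_ + b_
        return float(np.sum(y_col * lin - rho)) - ridge * float(a_ @ a_)

    ab = np.concatenate([a, [b0]])
    f0 = obj(ab)
    for _ in range(max_newton):
        a_, b_ = ab[:K], ab[K]
        eta = Mu @ a_ + b_ + 0.5 * Sd @ (a_**2)
        rho = np.exp(np.clip(eta, -50, 50))
        U = Mu + Sd * a_[None, :]  # d eta / d a
        grad = np.empty(K + 1)
        grad[:K] = y_col @ Mu - rho @ U - 2.0 * ridge * a_
        grad[K] = float(np.sum(y_col - rho))
        H = np.empty((K + 1, K + 1))
        H[:K, :K] = -(U.T @ (U * rho[:, None])) - np.diag(rho @ Sd) - 2.0 * ridge * np.eye(K)
        H[:K, K] = H[K, :K] = -(rho @ U)
        H[K, K] = -float(np.sum(rho))
        try:
            step = linalg.solve(-H, grad, assume_a="pos")
        except linalg.LinAlgError:
            break
        alpha = 1.0
        improved = False
        for _ in range(8):
            cand = ab + alpha * step
            f1 = obj(cand)
            if f1 >= f0:
                ab, f0, improved = cand, f1, True
                break
            alpha *= 0.5
        if not improved:
            break
    return ab[:K], float(ab[K]), f0


def _init_loadings(counts: list[np.ndarray], K: int, rng: np.random.Generator):
    """PCA of square-root-transformed, lightly smoothed counts."""
    from ._util import boxcar_smooth

    stacked = np.concatenate(counts, axis=0).astype(float)
    smoothed = boxcar_smooth(np.sqrt(stacked), 5, axis=0)
    centered = smoothed - smoothed.mean(axis=0)
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    A = Vt[:K].T * (s[:K] / np.sqrt(len(stacked)))[None, :]
    A = A + 0.01 * rng.standard_normal(A.shape)
    mean_rate = stacked.mean(axis=0)
    b = np.log(np.maximum(mean_rate, 1e-3))
    return A, b


def fit_latents(
    counts: list[np.ndarray] | SessionBundle,
    K: int = 4,
    bin_s: float = 0.010,
    gp_lengthscale_s: float = 0.100,
    gp_variance: float = 1.0,
    ridge: float = 1e-3,
    max_iter: int = 50,
    tol: float = 1e-6,
    n_restarts: int = 2,
    seed: int = 0,
) -> tuple[LatentModel, LatentTrajectories, dict]:
    """Variational EM fit of the GP-Poisson latent factor model.

    ``counts`` is either a :class:`SessionBundle` (binned over the
    target-onset-to-reward window) or a precomputed list of per-trial
    (T_r, n_units) count arrays. Returns the model, the per-trial
    posterior-mean trajectories (with marginal variances), and an info
    dict holding the ELBO trace and convergence flag. Multiple restarts
    (perturbed initializations) guard against local optima; the restart
    with the highest final ELBO wins.
    """
    if isinstance(counts, SessionBundle):
        counts = bin_session_counts(counts, bin_s=bin_s)
    n_units = counts[0].shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_units < K:
        import warnings

        warnings.warn(f"only {n_units} units for K={K} factors", stacklevel=2)
    prior = _PriorCache(bin_s, gp_lengthscale_s, gp_variance)

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(seed + restart)
        A, b = _init_loadings(counts, K, rng)
        state = _VarState(counts, K, prior)
        trace = [_elbo(counts, state, A, b, ridge)]
        converged = False
        for _ in range(max_iter):
            # E-step: means then covariances, one dimension at a time
            for r, y in enumerate(counts):
                T = y.shape[0]
                Kinv, _ = prior.get(T)
                for k in range(K):
                    state.mu[r][:, k] = _update_mu(
                        y, state.mu[r], state.sdiag[r], A, b, k, Kinv
                    )
                    # fixed-point covariance update, accepted only if the
                    # trial ELBO does not decrease
                    eta = state.mu[r] @ A.T + b
                    rho = np.exp(np.clip(eta + 0.5 * state.sdiag[r] @ (A.T**2), -50, 50))
                    w_new = rho @ (A[:, k] ** 2)
                    old_w = state.w[r][:, k].copy()
                    old_sd = state.sdiag[r][:, k].copy()
                    old_kl = state.kl[r][k]
                    old_obj = _trial_loglik(y, state.mu[r], state.sdiag[r], A, b) - np.sum(state.kl[r])
                    state.w[r][:, k] = w_new
                    state.refresh_trial_dim(r, k)
                    new_obj = _trial_loglik(y, state.mu[r], state.sdiag[r], A, b) - np.sum(state.kl[r])
                    if new_obj < old_obj - 1e-10:
                        state.w[r][:, k] = old_w
                        state.sdiag[r][:, k] = old_sd
                        state.kl[r][k] = old_kl
                    else:
                        # KL term must track the new mean even if w kept
                        state.refresh_trial_dim(r, k)
            # M-step: per-unit loading/bias Newton updates
            Mu = np.concatenate([m for m in state.mu], axis=0)
            Sd = np.concatenate([s for s in state.sdiag], axis=0)
            Y = np.concatenate(counts, axis=0)
            for n in range(n_units):
                A[n], b[n], _ = _update_unit(Y[:, n], Mu, Sd, A[n], b[n], ridge)
            # refresh KL after mean updates (covariances unchanged here)
            for r in range(len(counts)):
                for k in range(K):
                    state.refresh_trial_dim(r, k)
            trace.append(_elbo(counts, state, A, b, ridge))
            if abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
                converged = True
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], A.copy(), b.copy(), state, trace, converged)

    _, A, b, state, trace, converged = best
    model = LatentModel(
        loading=A, bias=b, K=K, gp_lengthscale_s=gp_lengthscale_s,
        gp_variance=gp_variance, bin_s=bin_s, ridge=ridge,
    )
    traj = LatentTrajectories(
        means=[m.copy() for m in state.mu],
        variances=[s.copy() for s in state.sdiag],
        bin_s=bin_s,
    )
    info = {"elbo_trace": np.array(trace), "converged": converged}
    return model, traj, info


def fit_loadings_given_latents(
    counts: list[np.ndarray],
    latents: list[np.ndarray],
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit Poisson regression of counts on known latent trajectories.

    With the latents clamped the model reduces to independent Poisson
    GLMs; returns (loading, bias, loading standard errors from the
    observed information).
    """
    Y = np.concatenate(counts, axis=0)
    Mu = np.concatenate(latents, axis=0)
    Sd = np.zeros_like(Mu)
    n_units, K = Y.shape[1], Mu.shape[1]
    A = np.zeros((n_units, K))
    b = np.log(np.maximum(Y.mean(axis=0), 1e-3))
    se = np.zeros((n_units, K))
    for n in range(n_units):
        A[n], b[n], _ = _update_unit(Y[:, n], Mu, Sd, A[n], b[n], ridge, max_newton=25)
        rho = np.exp(np.clip(Mu @ A[n] + b[n], -50, 50))
        X = np.column_stack([Mu, np.ones(len(Mu))])
        info_mat = X.T @ (X * rho[:, None])
        cov = np.linalg.inv(info_mat + 2 * ridge * np.eye(K + 1))
        se[n] = np.sqrt(np.diag(cov)[:K])
    return A, b, se


def infer_latents(
    counts: list[np.ndarray],
    model: LatentModel,
    unit_mask: np.ndarray | None = None,
    max_iter: int = 8,
) -> LatentTrajectories:
    """E-step only: infer posterior latents under a fixed model.

    ``unit_mask`` selects the units whose spikes drive the inference
    (used by leave-one-neuron-out prediction).
    """
    mask = np.ones(model.loading.shape[0], bool) if unit_mask is None else unit_mask
    A = model.loading[mask]
    b = model.bias[mask]
    prior = _PriorCache(model.bin_s, model.gp_lengthscale_s, model.gp_variance)
    sub = [y[:, mask] for y in counts]
    state = _VarState(sub, model.K, prior)
    for _ in range(max_iter):
        for r, y in enumerate(sub):
            Kinv, _ = prior.get(y.shape[0])
            for k in range(model.K):
                state.mu[r][:, k] = _update_mu(
                    y, state.mu[r], state.sdiag[r], A, b, k, Kinv
                )
                eta = state.mu[r] @ A.T + b
                rho = np.exp(np.clip(eta + 0.5 * state.sdiag[r] @ (A.T**2), -50, 50))
                state.w[r][:, k] = rho @ (A[:, k] ** 2)
                state.refresh_trial_dim(r, k)
    return LatentTrajectories(
        means=[m.copy() for m in state.mu],
        variances=[s.copy() for s in state.sdiag],
        bin_s=model.bin_s,
    )


def heldout_unit_loglik(
    counts: list[np.ndarray], model: LatentModel, unit: int, max_iter: int = 8
) -> float:
    """Poisson log-likelihood of one unit's counts predicted from the rest."""
    mask = np.ones(model.loading.shape[0], bool)
    mask[unit] = False
    traj = infer_latents(counts, model, unit_mask=mask, max_iter=max_iter)
    a, b0 = model.loading[unit], model.bias[unit]
    total = 0.0
    for y, mu, sd in zip(counts, traj.means, traj.variances):
        eta = mu @ a + b0
        rho = np.exp(np.clip(eta + 0.5 * sd @ (a**2), -50, 50))
        total += float(np.sum(y[:, unit] * eta - rho))
    return total


def select_dimensionality(
    counts: list[np.ndarray] | SessionBundle,
    K_candidates: tuple[int, ...] = (1, 2, 3, 4),
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, dict]:
    """Leave-one-neuron-out cross-validated choice of the factor count.

    For each candidate K the model is fit once; each unit's activity is
    then predicted from latents inferred with that unit held out. The K
    maximizing the summed held-out Poisson log-likelihood wins; ties break
    toward the smaller K.
    """
    if isinstance(counts, SessionBundle):
        counts = bin_session_counts(counts)
    n_units = counts[0].shape[1]
    cands = sorted(k for k in K_candidates if 1 <= k <= n_units - 1)
    if not cands:
        raise ValueError("no admissible K candidates")
    scores: dict[int, float] = {}
    for K in cands:
        model, _, _ = fit_latents(counts, K=K, seed=seed, **fit_kwargs)
        scores[K] = sum(heldout_unit_loglik(counts, model, n) for n in range(n_units))
    best = max(cands, key=lambda k: (scores[k], -k))
    return best, {"loo_loglik": scores}


def rotate_to_task(
    trajectories: LatentTrajectories,
    pta_weights: np.ndarray,
    model: LatentModel | None = None,
    d_prime: np.ndarray | None = None,
) -> tuple[LatentTrajectories, LatentModel | None]:
    """Rotate factors so the stimulus-driven signal concentrates in dim 1.

    ``pta_weights`` is the (28, K) PTA regression weight matrix; from the
    SVD ``W^T = U S V^T`` the factors are rotated to ``U^T x``, sorting
    dimensions by task explanatory power. The loading matrix, if given,
    is rotated compatibly (``A -> A U``) so per-bin rates are unchanged.
    When ``d_prime`` is provided, the stimulus axis's sign is chosen so
    the rotated loadings correlate positively with d'.
    """
    if trajectories.rotated:
        raise ValueError("trajectories are already rotated")
    W = np.asarray(pta_weights, dtype=float)
    U, _, _ = np.linalg.svd(W.T, full_matrices=True)  # (K, K)
    if d_prime is not None and model is not None:
        a_stim = model.loading @ U[:, 0]
        if np.dot(a_stim, d_prime) < 0:
            U = U.copy()
            U[:, 0] *= -1.0
    means = [m @ U for m in trajectories.means]
    variances = [v @ (U**2) for v in trajectories.variances]
    rotated = LatentTrajectories(
        means=means, variances=variances, bin_s=trajectories.bin_s,
        rotated=True, rotation=U.T,
    )
    rot_model = None
    if model is not None:
        rot_model = replace(model, loading=model.loading @ U)
    return rotated, rot_model
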