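import numpy as np
import pytest

from pulsepop import synth


@pytest.fixture(scope="session")
def spike_session():
    """A medium session with stimulus gain decay and a real choice latent."""
    pop = synth.PopulationSpec(
        n_units=16, choice_amplitude=0.5, gain_profile=synth.decaying_gain
    )
    return synth.simulate_session(
        600, "flat", pop=pop, rng=21, frozen_fraction=0.10, spike_window="stimulus"
    )


@pytest.fixture(scope="session")
def small_session():
    """A small session for I/O and pipeline tests."""
    pop = synth.PopulationSpec(n_units=8, choice_amplitude=0.3)
    return synth.simulate_session(120, "late", pop=pop, rng=3, spike_window="stimulus")


@pytest.fixture(scope="session")
def gp_poisson_data():
    """Counts simulated exactly from the GP-Poisson generative model (K=2)."""
    from scipy.linalg import cholesky

    from pulsepop import latents

    rng = np.random.default_rng(10)
    n_units, K, T, n_trials = 12, 2, 50, 50
    Kmat = latents.se_covariance(T, 0.01, 0.1, 1.0)
    L = cholesky(Kmat, lower=True)
    A = rng.normal(0, 0.4, (n_units, K))
    b = np.log(rng.uniform(0.1, 0.4, n_units))
    counts, lat = [], []
    for _ in range(n_trials):
        x = L @ rng.standard_normal((T, K))
        counts.append(rng.poisson(np.exp(x @ A.T + b)).astype(float))
        lat.append(x)
    return {"counts": counts, "latents": lat, "A": A, "b": b, "T": T}
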