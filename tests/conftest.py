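import numpy as np
import pytest

from omicox import SurvivalOutcome


def make_cox_instance(n, p, beta=None, seed=0, scale=50.0, censor_horizon=120.0):
    """Small simulated Cox cohort with exponential baseline and uniform
    censoring; returns (X, outcome, beta_true)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
    beta = np.asarray(beta, float)
    eta = X @ beta
    T = rng.exponential(scale * np.exp(-eta))
    C = rng.uniform(0, censor_horizon, n)
    time = np.minimum(T, C) + 1e-9 * np.arange(n)  # tie-free
    event = (T <= C).astype(int)
    if event.sum() < 2:  # pragma: no cover - guard for pathological seeds
        event[:2] = 1
    return X, SurvivalOutcome(time, event), beta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance():
    return make_cox_instance(50, 3, beta=[0.8, -0.5, 0.0], seed=1)
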