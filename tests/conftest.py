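import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bmitrans as bt

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth_params() -> bt.ModelParams:
    """The packaged reference coefficient set used as generating truth."""
    return bt.ModelParams.reference_smle()


@pytest.fixture(scope="session")
def cohort_small(truth_params) -> "bt.pd.DataFrame":
    """A 4,000-child two-wave cohort at the default generator settings."""
    return bt.generate_cohort(bt.CohortConfig(n=4000, seed=11), params=truth_params)


@pytest.fixture(scope="session")
def cohort_medium(truth_params):
    """A 20,000-child two-wave cohort for the heavier statistical checks."""
    return bt.generate_cohort(bt.CohortConfig(n=20000, seed=101), params=truth_params)


@pytest.fixture(scope="session")
def ref_tables():
    """Published transition counts of the motivating cohort, by stratum."""
    return bt.reference_transition_tables()


@pytest.fixture(scope="session")
def tiny_multinomial_instance():
    """A 50-record, 2-predictor multinomial instance with a known simulating
    truth, shared by the direct-maximization oracle tests."""
    rng = np.random.default_rng(3)
    n = 50
    X = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
    beta_true = np.array([[-0.5, 0.6, -0.4], [0.2, -0.3, 0.5], [0.1, 0.4, 0.3]])
    eta = np.zeros((n, 4))
    eta[:, [0, 2, 3]] = X @ beta_true.T
    P = np.exp(eta - eta.max(1, keepdims=True))
    P /= P.sum(1, keepdims=True)
    u = rng.random(n)
    y = 1 + (u[:, None] > np.cumsum(P, 1)[:, :3]).sum(1)
    return X, y
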