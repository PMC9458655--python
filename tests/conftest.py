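import numpy as np
import pytest

from clonalshift.config import SimulationConfig
from clonalshift.simulate import simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-sized cohort under default study conditions, shared across tests."""
    return simulate_cohort(SimulationConfig(n_samples=2000, seed=1))


@pytest.fixture(scope="session")
def large_cohort():
    """10k samples for moment checks on configured frequencies."""
    return simulate_cohort(SimulationConfig(n_samples=10_000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))
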