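import numpy as np
import pytest

from omcd.core import MCDParams
from omcd.experiments import solve_online_policy


@pytest.fixture(scope="session")
def ref_params() -> MCDParams:
    """Reference decision parameters used throughout the studies."""
    return MCDParams()  # R=1, alpha=0.2, nu=0.5, beta=1, gamma=4, kappa=0.01


@pytest.fixture(scope="session")
def ref_policy(ref_params):
    """Solved stopping thresholds at the reference parameters."""
    return solve_online_policy(ref_params).policy


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
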