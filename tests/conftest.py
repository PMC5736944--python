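import numpy as np
import pytest

from mph import SyntheticSpec, simulate, simulate_null

# lean factorization settings shared by tests that refit many times
LEAN_FIT = dict(n_restarts=3, max_iter=300, tol=1e-5)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 500 genes, 6 samples, 2 subpopulations
    mixed (0.7, 0.3)/(0.3, 0.7), 12 planted markers per subpopulation."""
    return simulate(SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def null_dataset():
    """Homogeneous data (single profile), same shape as the default."""
    return simulate_null(SyntheticSpec(seed=5))


@pytest.fixture(scope="session")
def quiet_dataset():
    """Near-noiseless mixture (precision fixed at 1e6)."""
    return simulate(SyntheticSpec(seed=3, fixed_lambda=1e6))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
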