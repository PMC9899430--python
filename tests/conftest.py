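import numpy as np
import pytest
from hypothesis import settings

from densvar import GompertzParams, MCMCSettings, simulate_gompertz

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCSettings:
    """Reduced sampler budget for unit tests (not the experiment defaults)."""
    return MCMCSettings(n_chains=3, n_iter=4_000, n_burn=1_500, seed=99)


@pytest.fixture(scope="session")
def gompertz_cell_params() -> GompertzParams:
    """The strongest-feedback design cell: beta = 0.6, sigma2 = 0.10."""
    return GompertzParams(r=0.4, k=1.0, sigma2=0.10)


@pytest.fixture(scope="session")
def stationary_series(gompertz_cell_params) -> np.ndarray:
    """A retained 100-point stationary segment from the beta=0.6 cell."""
    traj = simulate_gompertz(gompertz_cell_params, 1.0, 300, seed=42, n_discard=200)
    return traj.values[201:]
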