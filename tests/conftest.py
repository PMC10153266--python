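import numpy as np
import pytest

from mesi import ExposureSet, SimulationGrid, exposure_set, simulate_curves


@pytest.fixture(scope="session")
def log_ladder() -> ExposureSet:
    return exposure_set("logspaced", 20, 20e-6, 650e-3)


@pytest.fixture(scope="session")
def typical_ladder() -> ExposureSet:
    return exposure_set("typical")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_inrange_grid():
    """Clean, exposure-supported vessel grid for recovery checks."""
    return SimulationGrid(
        inv_tau_c=np.logspace(2, 4, 15), rho=np.linspace(0.6, 1.0, 7)
    )


@pytest.fixture(scope="session")
def small_inrange_stack(small_inrange_grid, log_ladder):
    stack, truth = simulate_curves(small_inrange_grid, log_ladder)
    return stack, truth
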