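import numpy as np
import pytest

from causalflow.datatypes import EnsembleTimeSeries, SimulatorParams
from causalflow.simulator import simulate_network


@pytest.fixture(scope="session")
def short_params() -> SimulatorParams:
    """Desk-scale simulation: 40 time units post-transient, default physics."""
    return SimulatorParams(duration=60.0, transient=20.0, seed=7)


@pytest.fixture(scope="session")
def short_run(short_params) -> EnsembleTimeSeries:
    return simulate_network(short_params)


@pytest.fixture(scope="session")
def rossler_series() -> np.ndarray:
    """One chaotic driver coordinate, binned to the analysis step."""
    p = SimulatorParams(duration=120.0, transient=20.0, seed=3, n_y=1)
    return simulate_network(p).bin(0.1).series("x1")


@pytest.fixture(scope="session")
def coupled_pair() -> EnsembleTimeSeries:
    """Unidirectionally coupled logistic maps (driver -> driven).

    Shared convention fixture for CF and every baseline: the influence of the
    driver on the driven unit must land in entry [row=driven, col=driver].
    A dynamical (not white-noise) driver is required so that cross-mapping,
    which reconstructs the driver's attractor from the driven unit, applies.
    """
    rng = np.random.default_rng(11)
    T, g = 2000, 0.32
    x, y = rng.uniform(0.2, 0.8, 2)
    X, Y = np.empty(T), np.empty(T)
    for t in range(T + 200):
        x, y = x * (3.8 - 3.8 * x), y * (3.5 - 3.5 * y - g * x)
        if t >= 200:
            X[t - 200], Y[t - 200] = x, y
    return EnsembleTimeSeries(np.vstack([X, Y]), dt=1.0, unit_ids=["driver", "driven"])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
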