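import numpy as np
import pytest

from rscm import ModelParameters, ModelState, simulate


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def default_init():
    return ModelState()


@pytest.fixture(scope="session")
def default_traj(default_params, default_init):
    """The canonical 20-day batch run on the 0.01-day grid."""
    return simulate(default_params, default_init, horizon=20.0, grid_step=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170929)


def random_states(rng, n):
    """Random non-negative state vectors spanning the dynamic ranges."""
    scales = np.array([70.0, 20.0, 10.0, 10.0, 10.0, 5.0,
                       1.0, 1.0, 0.5, 0.5, 1.0, 1.0])
    return rng.uniform(0.0, 1.0, size=(n, 12)) * scales
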