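import numpy as np
import pytest

from oxanox import EcosystemState, RedoxModel, default_parameters

# the two published initial-condition sets that demonstrate bistability:
# anoxic-leaning (sparse cyanobacteria, dense anaerobes, sulfidic) and
# oxic-leaning (dense cyanobacteria, sparse anaerobes, oxygenated)
ANOXIC_IC = dict(N_CB=5e1, N_PB=1e7, N_SB=1e7, S_O=300.0, S_R=300.0, O=10.0, P=10.0)
OXIC_IC = dict(N_CB=1e8, N_PB=1e2, N_SB=1e2, S_O=500.0, S_R=50.0, O=300.0, P=4.0)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def model(params):
    return RedoxModel(params)


@pytest.fixture
def anoxic_ic():
    return EcosystemState(**ANOXIC_IC)


@pytest.fixture
def oxic_ic():
    return EcosystemState(**OXIC_IC)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


def random_states(rng, n, with_zeros=False):
    """Random non-negative states with realistic magnitudes: populations up
    to 1e9 cells/L, substrates up to 1e3 uM."""
    states = np.empty((n, 7))
    states[:, :3] = 10 ** rng.uniform(0, 9, size=(n, 3))
    states[:, 3:] = 10 ** rng.uniform(-3, 3, size=(n, 4))
    if with_zeros:
        mask = rng.random(states.shape) < 0.1
        states[mask] = 0.0
    return states


def random_params(rng):
    """A random valid parameter set in loosely realistic ranges."""
    base = default_parameters()
    d = base.to_dict()
    for k in d:
        d[k] = d[k] * 10 ** rng.uniform(-0.5, 0.5) if d[k] > 0 else 0.0
    return type(base)(**d)
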