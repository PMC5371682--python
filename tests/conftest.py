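import numpy as np
import pytest

from stpnet import NetworkParams
from stpnet.presets import load_presets


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture
def params_E():
    """Excitatory single network inside its oscillatory window."""
    return NetworkParams.single("E", 2.0, -1.0, 2.5)


@pytest.fixture
def params_I():
    """Inhibitory single network inside its oscillatory window."""
    return NetworkParams.single("I", -10.0, 1.0, 2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_admissible_state(rng, n=None):
    """Random macroscopic states satisfying the bounds invariants."""
    shape = (8,) if n is None else (n, 8)
    omega = np.empty(shape)
    omega[..., 0:2] = rng.uniform(0.01, 0.99, shape[:-1] + (2,))
    omega[..., 2:4] = rng.uniform(0.0, 3.0, shape[:-1] + (2,))
    omega[..., 4:6] = rng.uniform(0.01, 1.0, shape[:-1] + (2,))
    omega[..., 6:8] = rng.uniform(0.01, 1.0, shape[:-1] + (2,))
    return omega
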