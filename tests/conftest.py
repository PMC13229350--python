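import numpy as np
import pytest

from pfceeg import build_circuit, default_config


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_cfg():
    """250-neuron circuit for fast simulation tests."""

    cfg = default_config()
    cfg.n_neurons = 250
    return cfg


@pytest.fixture(scope="session")
def circuit(default_cfg):
    return build_circuit(default_cfg, seed=12345)


@pytest.fixture(scope="session")
def small_circuit(small_cfg):
    return build_circuit(small_cfg, seed=54321)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
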