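import numpy as np
import pytest

from trnafret.synthdata import SimConfig, make_neuron_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_geometry():
    cfg = SimConfig(seed=7)
    return cfg, make_neuron_geometry(cfg)
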