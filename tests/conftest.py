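import numpy as np
import pytest

from slugflow.config import default_config
from slugflow.design_space import default_doe_space, default_selfopt_space
from slugflow.synthetic_reactor import ImpurityChannels, NoiseSpec, default_stocks


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def selfopt_space():
    return default_selfopt_space()


@pytest.fixture(scope="session")
def doe_space():
    return default_doe_space()


@pytest.fixture(scope="session")
def stocks():
    return default_stocks()


@pytest.fixture(scope="session")
def true_params(cfg):
    return cfg.true_params


@pytest.fixture
def noise():
    return NoiseSpec(rel_sd=0.02)


@pytest.fixture
def noise_free():
    return NoiseSpec(rel_sd=0.0)


@pytest.fixture
def no_impurities():
    """Impurity channels switched off: the reactor then reproduces the
    kinetic model exactly (used for parameter-recovery studies)."""
    return ImpurityChannels(nb_scale=0.0, unk_scale=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
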