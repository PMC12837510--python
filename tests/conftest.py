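import numpy as np
import pytest

from cssl_ct import MAEConfig, MaskedAutoencoder, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    return MAEConfig()


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    """An untrained tiny model shared across read-only tests."""
    return MaskedAutoencoder(tiny_config, rng=np.random.default_rng(12345))


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_spec():
    hu = {k: (mu, 0.0) for k, (mu, _) in PhantomSpec().tissue_hu.items()}
    return PhantomSpec(tissue_hu=hu)
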