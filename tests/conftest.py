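import numpy as np
import pytest

import sinlif as sl


@pytest.fixture(scope="session")
def supra():
    return sl.get_preset("supra")


@pytest.fixture(scope="session")
def supersinusoidal():
    return sl.get_preset("supersinusoidal")


@pytest.fixture(scope="session")
def critical():
    return sl.get_preset("critical")


@pytest.fixture(scope="session")
def subthreshold():
    return sl.get_preset("subthreshold")


@pytest.fixture(scope="session")
def supra_train(supra):
    """One N=1000 supra-threshold train, shared across tests."""
    return sl.simulate_train(supra, 1000, seed=301)


@pytest.fixture(scope="session")
def supersin_train(supersinusoidal):
    """One N=1000 supersinusoidal train, shared across tests."""
    return sl.simulate_train(supersinusoidal, 1000, seed=302)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
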