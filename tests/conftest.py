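import numpy as np
import pytest

from cernet.novel import toy_model, toy_training_set
from cernet.simulate import demo_config, simulate_all


@pytest.fixture(scope="session")
def cp_model():
    return toy_model(seed=0)


@pytest.fixture(scope="session")
def cp_training():
    return toy_training_set(seed=0)


@pytest.fixture(scope="session")
def demo_bundle():
    """The bundled demonstration dataset (seed 7), shared across tests."""
    return simulate_all(demo_config(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
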