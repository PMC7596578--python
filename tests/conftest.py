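import numpy as np
import pytest

from hbocscreen import base_parameter_set, default_curves, make_toy_model


@pytest.fixture(scope="session")
def base_params():
    return base_parameter_set()


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def toy():
    return make_toy_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
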