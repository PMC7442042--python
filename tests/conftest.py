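import numpy as np
import pytest

from bmbands.design import eigen_system, make_design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def grid50():
    return make_design(50)


@pytest.fixture(scope="session")
def basis50():
    return eigen_system(50)


@pytest.fixture(scope="session")
def basis200():
    return eigen_system(200)
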