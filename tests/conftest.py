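import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bphpkit.synth import (
    bphp1_basis,
    bphp1_params,
    bphp2_basis,
    bphp2_params,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis_bphp1():
    return bphp1_basis()


@pytest.fixture(scope="session")
def basis_bphp2():
    return bphp2_basis()


@pytest.fixture(scope="session")
def params_bphp1():
    return bphp1_params()


@pytest.fixture(scope="session")
def params_bphp2():
    return bphp2_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20190311)
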