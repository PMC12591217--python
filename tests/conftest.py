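import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beadops import fixtures, mechanics, protocol

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def unit_params():
    return mechanics.ForceParams(k_mag=1.0, k_int=1.0, k_fric=1.0)


@pytest.fixture
def default_layout():
    return fixtures.default_layout()


@pytest.fixture
def default_program(default_layout):
    return protocol.default_ime_program(default_layout)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
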