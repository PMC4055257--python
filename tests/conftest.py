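import numpy as np
import pytest

from rotob1 import (
    GAMMA_PROTON,
    GridSpec,
    calibrate_amplitude,
    gauss_pulse,
    linear_gradient_map,
    make_mask,
    make_shepp_logan,
)


@pytest.fixture(scope="session")
def grid16():
    return GridSpec(16, 16, 1, 5e-3)


@pytest.fixture(scope="session")
def grid32():
    return GridSpec(32, 32, 1, 5e-3)


@pytest.fixture(scope="session")
def shepp16(grid16):
    return make_shepp_logan(grid16)


@pytest.fixture(scope="session")
def shepp32(grid32):
    return make_shepp_logan(grid32)


@pytest.fixture(scope="session")
def mask16(shepp16):
    return make_mask(shepp16, 0.0)


@pytest.fixture(scope="session")
def mask32(shepp32):
    return make_mask(shepp32, 0.0)


@pytest.fixture(scope="session")
def pulse5ms():
    return gauss_pulse(5e-3, 256, 0.5)


@pytest.fixture(scope="session")
def linmap16(grid16):
    return linear_gradient_map(grid16, 37.5e-9)


@pytest.fixture(scope="session")
def cal16(pulse5ms, linmap16):
    return calibrate_amplitude(pulse5ms, 16, linmap16.peak, GAMMA_PROTON, 90.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
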