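import numpy as np
import pytest

from ultrabeam import Pulse, make_linear_array


@pytest.fixture
def geometry():
    """Standard 64-element 5 MHz array, half-wavelength pitch."""
    return make_linear_array(64, 0.154, 5e6, 40e6, 1540.0)


@pytest.fixture
def small_geometry():
    return make_linear_array(8, 0.2, 5e6, 40e6, 1540.0)


@pytest.fixture
def pulse():
    return Pulse(center_frequency=5e6, fractional_bandwidth=0.6, duration_cycles=2.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_hermitian(rng, n, psd=False):
    a = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    if psd:
        return a @ a.conj().T / n
    return 0.5 * (a + a.conj().T)


def random_pd(rng, n, loading=0.1):
    return random_hermitian(rng, n, psd=True) + loading * np.eye(n)
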