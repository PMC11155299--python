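import numpy as np
import pytest

from sbsd.phantom import AcquisitionScheme, default_kernel_bank, make_scheme
from sbsd.stage1_omp import build_dictionary


def fibonacci_sphere(n: int) -> np.ndarray:
    """Full-sphere spiral grid used as a dense quadrature-like sampling."""
    i = np.arange(n)
    z = 1.0 - (2 * i + 1) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@pytest.fixture(scope="session")
def bank():
    return default_kernel_bank()


@pytest.fixture(scope="session")
def scheme130():
    return make_scheme(130, 3000.0, seed=1)


@pytest.fixture(scope="session")
def scheme150_b5000():
    return make_scheme(150, 5000.0, seed=1)


@pytest.fixture(scope="session")
def dense_scheme():
    """Dense full-sphere scheme for truncation-limited checks."""
    return AcquisitionScheme(3000.0, fibonacci_sphere(2000))


@pytest.fixture(scope="session")
def dict4():
    return build_dictionary(4)


@pytest.fixture(scope="session")
def dict6():
    return build_dictionary(6)


@pytest.fixture(scope="session")
def dict8():
    return build_dictionary(8)
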