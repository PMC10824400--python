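import numpy as np
import pytest

from synthrr import (
    ActivityImage,
    ProjectionGeometry,
    gaussian_kernel,
    make_shepp_logan,
)


@pytest.fixture(scope="session")
def shepp32():
    return make_shepp_logan(32, 1.0)


@pytest.fixture(scope="session")
def geo32():
    return ProjectionGeometry.native(32, 1.0, 60)


@pytest.fixture(scope="session")
def psf_1mm():
    return gaussian_kernel(2.9, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230222)


@pytest.fixture
def random_image8(rng):
    return ActivityImage(rng.uniform(0.0, 1.0, (8, 8)), 1.0, label="random8")


def dense_matrix(op, n_in, n_out):
    """Materialise a linear operator column by column (independent oracle)."""
    A = np.zeros((n_out, n_in))
    for j in range(n_in):
        e = np.zeros(n_in)
        e[j] = 1.0
        A[:, j] = op(e)
    return A
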