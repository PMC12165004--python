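import numpy as np
import pytest

from shapegwas.synthetic import make_icosphere


@pytest.fixture(scope="session")
def icosphere2():
    """Unit icosphere, 162 vertices / 320 faces."""
    return make_icosphere(1.0, 2)


@pytest.fixture(scope="session")
def icosphere4():
    """Unit icosphere, 2562 vertices / 5120 faces."""
    return make_icosphere(1.0, 4)


@pytest.fixture(scope="session")
def icosphere4_spectrum(icosphere4):
    from shapegwas.spectrum import compute_shape_spectrum

    return compute_shape_spectrum(icosphere4, k=12)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
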