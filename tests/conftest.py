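import numpy as np
import pytest

from dwiharm import make_phantom


@pytest.fixture(scope="session")
def phantom24():
    """Noiseless 24^3 tensor phantom, 12 directions + 2 b0 volumes."""
    return make_phantom(shape=(24, 24, 24), n_dirs=12, rng_seed=7)


@pytest.fixture(scope="session")
def phantom_small():
    """Small 10^3 phantom for fast patch/IO tests."""
    return make_phantom(shape=(10, 10, 10), n_dirs=8, rng_seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_unit_dictionary(rng, m, p):
    D = rng.standard_normal((m, p))
    return D / np.linalg.norm(D, axis=0)
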