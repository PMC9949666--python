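import numpy as np
import pytest

import hypersig as hs


@pytest.fixture(scope="session")
def space():
    return hs.DEFAULT_SPACE


@pytest.fixture(scope="session")
def catalog():
    return hs.default_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_pair(rng, space):
    """One random (P, Q) strategy pair on the default grids."""
    P = hs.random_strategy((space.n_states, space.n_words), rng)
    Q = hs.random_strategy((space.n_words, space.n_actions), rng)
    return P, Q
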