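import numpy as np
import pytest

import ridgewalk as rw


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_nk(rng):
    """A rugged NK landscape small enough to enumerate exhaustively."""
    return rw.make_nk_landscape(L=8, K=4, rng=rng)


@pytest.fixture
def smooth_nk(rng):
    """A K=0 (multiplicative, epistasis-free) NK landscape."""
    return rw.make_nk_landscape(L=8, K=0, rng=rng)


@pytest.fixture
def rmf(rng):
    return rw.make_rmf_landscape(L=10, slope=0.25, rng=rng)
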