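import numpy as np
import pytest

from diffgoods import InitialCondition, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed16(rng):
    """A 16x16 50-50 random grid."""
    return make_grid(16, InitialCondition("mixed_50_50"), rng)


def random_grids(L, n, fraction=0.5, seed=0):
    """n independent i.i.d. Bernoulli(fraction) producer grids."""
    g = np.random.default_rng(seed)
    return [(g.random((L, L)) < fraction).astype(np.int8) for _ in range(n)]
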