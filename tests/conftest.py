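import numpy as np
import pytest

from latticetx import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A 20x20 lattice with the standard rates, short horizon."""
    return SimParams(l=20, n0=0.5, f_R=0.05, t_end=200.0, seed=7)
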