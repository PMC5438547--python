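import numpy as np
import pytest

from tstv import synthetic


@pytest.fixture(scope="session")
def shape_table():
    """Seeded synthetic pentamer shape table."""
    return synthetic.gen_shape_table(seed=101)


@pytest.fixture(scope="session")
def motif_library():
    """Small seeded synthetic motif library."""
    return synthetic.gen_motif_library(12, (5, 12), 0.5, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
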