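import numpy as np
import pytest

from pancmorph import SimParams, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# small, fast study system: fewer roots and a shorter growth window than the
# default 40-terminus condition, same rule set
FAST_PARAMS = SimParams(n_initial_termini=8, max_steps=250, seed=5)


@pytest.fixture(scope="session")
def small_network():
    return simulate(FAST_PARAMS)
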