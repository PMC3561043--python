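import numpy as np
import pytest

import urnlearn as ul

M4_PARAMS = dict(ul.DEFAULT_GENERATING_PARAMS["M4"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects simulated from M4 with the default generating params."""
    return ul.simulate_cohort(ul.TaskDesign(), 4, "M4", M4_PARAMS, seed=777)


@pytest.fixture(scope="session")
def one_session(small_cohort):
    return small_cohort[0]
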