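import numpy as np
import pytest

from flightpower import dove_analysis, make_morphology


@pytest.fixture(scope="session")
def dove():
    """Calibrated synthetic dove flight, fully analyzed (shared, seed 1)."""
    return dove_analysis(seed=1, n_wingbeats=4)


@pytest.fixture(scope="session")
def dove_morph():
    return make_morphology("dove")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
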