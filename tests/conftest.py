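import numpy as np
import pytest

from gazeperim.grid import build_grid
from gazeperim.observer import HillModel, ObserverBehavior, sample_observer


@pytest.fixture(scope="session")
def right_grid():
    return build_grid("right")


@pytest.fixture(scope="session")
def left_grid():
    return build_grid("left")


@pytest.fixture
def flat_hill():
    """Flat 20 dB field, no interobserver or pointwise noise."""
    return HillModel(peak_db=20.0, slope_db_per_deg=0.0,
                     interobserver_sd=0.0, pointwise_sd=0.0)


@pytest.fixture
def ideal_behavior():
    """No guesses, no lapses: frequency of seeing matches the likelihood."""
    return ObserverBehavior(fp_rate=0.0, fn_rate=0.0)


@pytest.fixture
def flat_observer(flat_hill, right_grid, ideal_behavior):
    return sample_observer(flat_hill, right_grid, ideal_behavior, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
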