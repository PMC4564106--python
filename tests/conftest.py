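import numpy as np
import pytest

from survarea import SurvivalDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20150909)


def random_survival_data(rng, n_max=30):
    """Small random censored dataset for oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    times = np.round(rng.exponential(10.0, size=n), 3)
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0 and n > 1:
        events[int(rng.integers(0, n))] = 1
    return SurvivalDataset(times, events)


@pytest.fixture
def toy_dataset():
    return SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 1])
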