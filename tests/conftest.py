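import numpy as np
import pytest

from spikevein import IntensityMaps, SpikeWave


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_maps(rng):
    """Random nonnegative intensity maps with a sprinkling of exact zeros."""
    data = rng.uniform(0, 255, size=(4, 9, 9))
    data[rng.random(data.shape) < 0.3] = 0.0
    return IntensityMaps(data=data)


def random_cumulative_spikes(rng, t_max, F, H, W, p_never=0.3):
    """Random cumulative spike wave from random first-spike times."""
    t_first = rng.integers(0, t_max, size=(F, H, W))
    never = rng.random((F, H, W)) < p_never
    steps = np.arange(t_max).reshape(-1, 1, 1, 1)
    s = ((steps >= t_first[None]) & ~never[None]).astype(np.uint8)
    return SpikeWave(s=s)
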