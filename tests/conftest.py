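import numpy as np
import pytest

from spikeconn import SpikeDataset, SpikeTrain


def poisson_train(rate, duration, seed, unit_id=0):
    """Homogeneous Poisson train (test helper)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n))
    return SpikeTrain(unit_id, times, 0.0, duration)


def poisson_pair(rate, duration, seed):
    return (poisson_train(rate, duration, seed, 0),
            poisson_train(rate, duration, seed + 10_000_000, 1))


@pytest.fixture
def small_dataset():
    """Three short hand-made trains on a shared 1-s span."""
    return SpikeDataset((
        SpikeTrain(0, [0.1, 0.3, 0.7], 0.0, 1.0),
        SpikeTrain(1, [0.2, 0.5], 0.0, 1.0),
        SpikeTrain(2, [0.15, 0.55, 0.9], 0.0, 1.0),
    ), 0.0, 1.0)
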