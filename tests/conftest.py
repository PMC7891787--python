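import numpy as np
import pytest

from seqpop.tensor import SpikeCountTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_tensor(rng):
    """Small random tensor: 4 cells x 12 bins x 10 reps, counts 0..3."""
    counts = rng.integers(0, 4, size=(4, 12, 10))
    return SpikeCountTensor(counts, bin_width=1000.0 / 60.0)


@pytest.fixture
def correlated_pair_tensor(rng):
    """Two cells with genuinely correlated trial-to-trial noise."""
    T, R = 30, 40
    shared = rng.poisson(0.6, size=(T, R))
    a = shared + rng.poisson(0.2, size=(T, R))
    b = shared + rng.poisson(0.2, size=(T, R))
    return SpikeCountTensor(np.stack([a, b]), bin_width=1000.0 / 60.0)
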