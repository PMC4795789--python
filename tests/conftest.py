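import numpy as np
import pytest

from nestnet import ActivityClassifier
from nestnet.simulate import gen_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Synthetic benchmark: raw sequences plus the 134/20/30/56 split."""
    return gen_benchmark(seed=7)


@pytest.fixture(scope="session")
def split(benchmark):
    return benchmark[1]


@pytest.fixture(scope="session")
def lrf_result(split):
    """One trained + calibrated local-receptive-field classifier."""
    return ActivityClassifier(split, variant="idnn-lrf").fit(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
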