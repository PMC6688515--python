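import numpy as np
import pytest

from posthoclab import make_benchmark_dataset


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Medium synthetic dataset with planted ground truth (shared, read-only)."""
    return make_benchmark_dataset(n_epochs=400, n_channels=20, n_background=10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
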