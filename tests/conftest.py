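import numpy as np
import pytest

from emgmeta import (Pool, STFTConfig, SynthConfig, generate_dataset,
                     make_fewshot_splits, preprocess_recording)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig.small(seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    return [preprocess_recording(r) for r in small_dataset]


@pytest.fixture(scope="session")
def subject_pools(small_samples):
    """Meta-train / val / test sample pools over disjoint subjects (6/1/1)."""
    return make_fewshot_splits(small_samples, range(6), [6], [7])


@pytest.fixture(scope="session")
def train_pool(subject_pools):
    return Pool.from_samples(subject_pools[0], "stft", STFTConfig())


@pytest.fixture(scope="session")
def test_pool(subject_pools):
    return Pool.from_samples(subject_pools[2], "stft", STFTConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
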