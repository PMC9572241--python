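import numpy as np
import pytest

import oodhar as oh


@pytest.fixture(scope="session")
def small_config():
    return oh.BenchmarkConfig(dataset_names=("A", "B", "C"), n_subjects=4,
                              activity_seconds=30.0)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return oh.make_benchmark(small_config, seed=42)


@pytest.fixture(scope="session")
def windowset(small_corpus):
    return oh.harmonize_corpus(small_corpus)


@pytest.fixture(scope="session")
def handcrafted(windowset):
    return oh.extract_features(windowset)


@pytest.fixture(scope="session")
def tasks(windowset):
    return oh.make_all_tasks(windowset, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
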