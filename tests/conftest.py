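import numpy as np
import pytest

from bifuse.network import compact_config
from bifuse.pipeline import make_subtrials, preprocess_pair
from bifuse.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A small but strongly lateralized synthetic participant."""
    return SyntheticSpec(n_trials_per_class=3, erd_depth=0.8, hemo_amplitude=1.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    eeg, fnirs = small_dataset
    return preprocess_pair(eeg, fnirs)


@pytest.fixture(scope="session")
def subtrials_b(small_pairs):
    return make_subtrials(small_pairs, "b", "hbo")


@pytest.fixture
def tiny_cfg():
    return compact_config()
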