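import numpy as np
import pytest

from spdfatigue.fusion import TrainConfig
from spdfatigue.synthetic import GenConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated multi-subject dataset shared across training tests."""
    cfg = GenConfig(n_subjects=4, trials_per_subject=(10, 14), separation=2.0, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_train_config():
    """Down-sized network so training tests stay fast."""
    return TrainConfig(hidden_size=16, d1=16, d2=8, maxite=20, seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset, small_train_config):
    from spdfatigue import fusion

    X, y, subj = small_dataset.labeled_arrays()
    covs, seqs = fusion.prepare_features(X, small_train_config)
    return covs, seqs, y, subj
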