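import numpy as np
import pytest

from m3net.encoders import EncoderConfig
from m3net.phantom import PhantomConfig, simulate_cohort
from m3net.training import TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 benign + 12 malignant cases, 2 frames each, generated in memory."""
    config = PhantomConfig(n_cases_benign=8, n_cases_malignant=12,
                           frames_per_case=2, seed=5)
    return config, simulate_cohort(config)


@pytest.fixture
def quick_train_config():
    """Desk-scale training settings for structural (non-learnability) tests."""
    return TrainConfig(input_size=16, max_epochs=8, early_stop_patience=6,
                       seed=3)


@pytest.fixture
def tiny_encoder_config():
    return EncoderConfig(backbone_name="tiny_cnn")
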