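import numpy as np
import pytest

from somnoseq import SyntheticConfig, generate_dataset
from somnoseq.model import CnnBranchConfig, CnnConfig, ModelConfig, SleepStager


@pytest.fixture(scope="session")
def small_dataset():
    """2 recordings x 60 epochs of default-spectra synthetic EEG."""
    cfg = SyntheticConfig(n_recordings=2, epochs_per_recording=60, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 4 x 240 synthetic bundle used for functional runs."""
    return generate_dataset(SyntheticConfig(seed=1))


def tiny_model_config(**overrides) -> ModelConfig:
    """A deliberately minuscule network for oracle and gradient tests."""
    kwargs = dict(
        cnn=CnnConfig(
            small=CnnBranchConfig(filters=(50, 4, 4, 4), strides=(6, 1, 1, 1),
                                  channels=(2, 2, 2, 2), pool_size=8),
            large=CnnBranchConfig(filters=(400, 4, 4, 4), strides=(50, 1, 1, 1),
                                  channels=(2, 2, 2, 2), pool_size=4),
            dropout=0.0,
        ),
        encoder_hidden=4,
        decoder_hidden=4,
        embed_dim=3,
        cell="lstm",
        init_seed=7,
    )
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


@pytest.fixture
def tiny_model() -> SleepStager:
    return SleepStager(tiny_model_config())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
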