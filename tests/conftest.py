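import numpy as np
import pytest
from hypothesis import settings

from edapain.fcn import ConvBlock, FcnConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from edapain.preprocess import build_dataset
from edapain.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A 4-subject cohort config: full-length recordings, fast to build."""
    return SynthConfig(n_subjects=4, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return build_dataset(small_cohort)


@pytest.fixture
def tiny_fcn_config() -> FcnConfig:
    """A miniature architecture for fast numerical tests."""
    return FcnConfig(
        input_len=50,
        conv_blocks=(ConvBlock(3, 2, "relu", True), ConvBlock(4, 3, "tanh", True)),
        avgpool_kernel=2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
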