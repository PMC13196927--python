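import numpy as np
import pytest

from ecgrecon.maskvae import LeadMask, ModelConfig, VaeModel
from ecgrecon.synthdata import NOISE_PROFILES, generate_dataset


@pytest.fixture(scope="session")
def clean_records():
    """Six noise-free subjects, one 4-second record each at 250 Hz."""
    return generate_dataset(6, 1, 4.0, 250.0, noise=NOISE_PROFILES["none"],
                            seed=123)


@pytest.fixture(scope="session")
def noisy_records():
    return generate_dataset(6, 2, 4.0, 250.0, noise=NOISE_PROFILES["default"],
                            seed=321)


@pytest.fixture
def mask3():
    return LeadMask.from_retained("II,V1,V5")


@pytest.fixture
def tiny_config():
    """Smallest config that still exercises every architectural element."""
    return ModelConfig(base_channels=16, bottleneck_channels=32,
                       n_down_stages=2, latent_dim=4, attention_heads=4,
                       groupnorm_groups=4, residual_blocks_per_stage=1)


@pytest.fixture
def tiny_model(tiny_config):
    return VaeModel(tiny_config, seed=0, dtype=np.float64)
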