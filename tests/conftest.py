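import numpy as np
import pytest

from vigilnet.encoder import EncoderConfig
from vigilnet.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 60 samples at the published modality shapes."""
    return generate_dataset(SimConfig(n_subjects=2, samples_per_subject=60, seed=11))


@pytest.fixture
def tiny_encoder_config():
    """A shrunken encoder for fast structural tests."""
    return EncoderConfig(in_features=10, n_steps=4, conv1_channels=6, conv2_channels=8,
                         d_model=8, attn_heads=2, ffn_dim=16, n_layers=1, dropout=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
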