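import numpy as np
import pytest

import calfuse as cf


@pytest.fixture(scope="session")
def separable_bundle():
    """Well-separated two-class, two-modality data: easy to learn, fast."""
    spec = cf.SyntheticSpec(n_samples=300, n_classes=2,
                            class_proportions=(0.5, 0.5), modality_dims=(4, 4),
                            class_separation=3.0, seed=5)
    return cf.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_encoder_config():
    return cf.EncoderConfig(modality_dims=(4, 4), n_classes=2, embed_dim=8,
                            n_layers=1, n_heads=2, dropout_rate=0.2, seed=0)


@pytest.fixture(scope="session")
def trained_model(separable_bundle, small_encoder_config):
    cfg = cf.TrainConfig(learning_rate=5e-3, max_epochs=15, patience=10, seed=0)
    return cf.fit(separable_bundle, small_encoder_config, cfg)
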