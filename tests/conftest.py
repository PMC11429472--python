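import numpy as np
import pytest

from fundusseg.encoder import EncoderConfig
from fundusseg.model import FundusTumorNet, ModelConfig
from fundusseg.synthetic import SynthConfig, generate_sample

MICRO_ENCODER = dict(micro_scale=4, window_size=4)


def micro_model_config(seed: int = 0, **encoder_kwargs) -> ModelConfig:
    kwargs = {**MICRO_ENCODER, **encoder_kwargs}
    return ModelConfig(encoder=EncoderConfig(**kwargs), seed=seed)


@pytest.fixture(scope="session")
def micro_model() -> FundusTumorNet:
    """Quarter-width model for 64-pixel inputs, shared across tests."""
    return FundusTumorNet(micro_model_config(seed=0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Eight 64-pixel synthetic samples (images, masks, labels)."""
    cfg = SynthConfig(image_size=64, n_images=8, seed=0)
    recs = [generate_sample(cfg, i) for i in range(cfg.n_images)]
    X = np.stack([r.image for r in recs])
    y = np.stack([r.mask for r in recs])
    labels = np.array([0 if r.label == "benign" else 1 for r in recs])
    return X, y, labels


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
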