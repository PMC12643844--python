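import numpy as np
import pytest

from miltext.classifier import ClassifierConfig, TrainConfig
from miltext.encoder import ToyEncoder
from miltext import synthgen as syn


@pytest.fixture(scope="session")
def toy_encoder():
    return ToyEncoder(n_blocks=4, dim=32, seed=0)


@pytest.fixture(scope="session")
def tiny_ccfg():
    return ClassifierConfig(L=4, d=32, windows=(2, 3), m=8, max_len=32)


@pytest.fixture()
def overfit_tcfg():
    """Full-batch training config that overfits small separable sets."""
    return TrainConfig(batch_size=64, learning_rate=0.01, patience_steps=100,
                       max_steps=500, folds=3, split=(0.8, 0.1, 0.1), seed=0)


@pytest.fixture(scope="session")
def synth_posts_small():
    cfg = syn.SynthConfig(n_posts=60, seed=11, p_related=0.5)
    return syn.gen_posts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
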