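import numpy as np
import pytest

import bgclm as bg


@pytest.fixture(scope="session")
def small_spec():
    return bg.SynthSpec(n_pfams=60, n_classes=3, signature_size=10,
                        background_size=20, bgc_length_range=(8, 16),
                        genome_length=120, n_implants=2,
                        signature_purity=0.8, seed=0)


@pytest.fixture(scope="session")
def small_vocab(small_spec):
    return bg.make_vocab(small_spec)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return bg.make_corpus(small_spec, 60, seed=7)


@pytest.fixture(scope="session")
def tiny_model(small_vocab):
    """Untrained small model for shape/score plumbing tests."""
    cfg = bg.ModelConfig(vocab_size=len(small_vocab), hidden_dim=16,
                         embed_dim=12, n_layers=3, max_dilation=4, seed=1)
    return bg.build_random_model(cfg, small_vocab)


class RandomLogitStub:
    """Seeded random-logit predictor over a vocabulary (scoring-path oracle aid)."""

    def __init__(self, vocab, seed=0, scale=3.0):
        self.vocab = vocab
        self.seed = seed
        self.scale = scale

    def __call__(self, tokens, pad_mask=None):
        tokens = np.asarray(tokens)
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.scale, size=tokens.shape + (len(self.vocab),))


@pytest.fixture
def random_logit_stub(small_vocab):
    return RandomLogitStub(small_vocab, seed=13)
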