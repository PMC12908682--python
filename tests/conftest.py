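import numpy as np
import pytest

from epintlm import EmbeddingTable, ModelConfig, EPINTLM


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(**overrides) -> ModelConfig:
    """A miniature architecture for fast unit tests: same wiring,
    non-canonical geometry (60/40-token elements)."""
    base = dict(embed_dim=4, conv_channels=6, conv_kernel=5, pool_kernel=3,
                gru_layers=2, gru_hidden_per_dir=4, attn_heads=2, dropout=0.0,
                classifier_hidden=8, genomic_dim=10,
                enhancer_tokens=60, promoter_tokens=40)
    base.update(overrides)
    return ModelConfig(**base)


def random_table(rng, dim=4, vocab_size=4097) -> EmbeddingTable:
    m = rng.normal(size=(vocab_size, dim)).astype(np.float32)
    m[-1] = 0.0
    return EmbeddingTable(matrix=m, provenance="test-random")


@pytest.fixture
def tiny_model(rng):
    cfg = tiny_config()
    return EPINTLM(cfg, random_table(rng, dim=cfg.embed_dim), seed=7)


@pytest.fixture
def tiny_batch(rng):
    B = 3
    return (rng.integers(0, 4097, (B, 60)), rng.integers(0, 4097, (B, 40)),
            rng.normal(size=(B, 10)).astype(np.float32))
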