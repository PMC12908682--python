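import numpy as np
import pytest

from _oracles import attention_oracle
from epintlm import EPINTLM, ModelConfig, bce_loss
from epintlm.model import reduced_config
from epintlm.nn import MultiHeadAttention, Tensor
from conftest import random_table, tiny_config


class TestConfig:
    def test_canonical_dimension_arithmetic(self):
        cfg = ModelConfig()
        assert cfg.pooled_length(2995) == 147
        assert cfg.pooled_length(1995) == 97
        assert cfg.model_dim == 64
        assert cfg.fused_flat_width == (147 + 97 + 1) * 64 == 15680

    def test_minimal_length_formula(self):
        cfg = ModelConfig()
        # 59 tokens: conv gives 20 positions, pooling gives 1
        assert cfg.pooled_length(59) == 1

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(attn_heads=5)

    def test_reduced_config_keeps_canonical_geometry(self):
        cfg = reduced_config()
        assert cfg.pooled_length(cfg.enhancer_tokens) == 147
        assert cfg.pooled_length(cfg.promoter_tokens) == 97


class TestAttentionOracles:
    """Both attention flavors must match a nested-loop implementation."""

    @pytest.mark.parametrize("case", range(10))
    def test_self_attention_matches_loop_oracle(self, case):
        rng = np.random.default_rng(100 + case)
        d, H = 4 * int(rng.integers(1, 4)), int(rng.integers(1, 3))
        if d % H:
            H = 1
        L, B = int(rng.integers(1, 6)), int(rng.integers(1, 4))
        layer = MultiHeadAttention(d, H, np.random.default_rng(case))
        x = rng.normal(size=(B, L, d))
        out, w = layer(Tensor(x.astype(np.float32)))
        ref_out, ref_w = attention_oracle(x, x, layer)
        assert np.allclose(out.data, ref_out, atol=1e-5)
        assert np.allclose(w, ref_w, atol=1e-5)

    @pytest.mark.parametrize("case", range(10))
    def test_cross_attention_matches_loop_oracle(self, case):
        rng = np.random.default_rng(200 + case)
        layer = MultiHeadAttention(8, 2, np.random.default_rng(case))
        Lq, Lk, B = int(rng.integers(1, 5)), int(rng.integers(1, 7)), 2
        xq = rng.normal(size=(B, Lq, 8))
        xkv = rng.normal(size=(B, Lk, 8))
        out, w = layer(Tensor(xq.astype(np.float32)),
                       Tensor(xkv.astype(np.float32)))
        ref_out, ref_w = attention_oracle(xq, xkv, layer)
        assert out.shape == (B, Lq, 8)
        assert w.shape == (B, 2, Lq, Lk)
        assert np.allclose(out.data, ref_out, atol=1e-5)
        assert np.allclose(w, ref_w, atol=1e-5)

    def test_single_position_attention_is_identity_weight(self, rng):
        """A length-1 input (the genomic vector) gets weight exactly 1,
        so attention reduces to the value/output projections."""
        layer = MultiHeadAttention(8, 2, np.random.default_rng(0))
        x = rng.normal(size=(3, 1, 8)).astype(np.float32)
        out, w = layer(Tensor(x))
        assert np.allclose(w, 1.0)
        v = layer.w_v(Tensor(x))
        expected = layer.w_o(v).data
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_identical_keys_make_output_query_independent(self, rng):
        layer = MultiHeadAttention(8, 2, np.random.default_rng(1))
        v = rng.normal(size=8).astype(np.float32)
        kv = np.broadcast_to(v, (2, 5, 8)).copy()
        for q_seed in (1, 2):
            q = rng.normal(size=(2, 3, 8)).astype(np.float32)
            out, w = layer(Tensor(q), Tensor(kv))
            assert np.allclose(w, 1.0 / 5, atol=1e-6)
            expected = layer.w_o(layer.w_v(Tensor(kv[:, :1, :]))).data
            assert np.allclose(out.data, np.broadcast_to(expected, out.shape),
                               atol=1e-5)


class TestForwardPass:
    def test_shapes_and_probability_range(self, tiny_model, tiny_batch):
        probs, _ = tiny_model(*tiny_batch)
        assert probs.shape == (3,)
        assert np.all((probs.data > 0) & (probs.data < 1))

    def test_attention_maps_returned_time_major(self, tiny_model, tiny_batch):
        cfg = tiny_model.config
        le = cfg.pooled_length(60)
        lp = cfg.pooled_length(40)
        _, maps = tiny_model(*tiny_batch, return_attention=True)
        assert maps["enh_to_pro"].shape == (2, 3, le, lp)
        assert maps["pro_to_enh"].shape == (2, 3, lp, le)
        assert maps["self_G"].shape == (2, 3, 1, 1)
        for m in maps.values():
            assert np.allclose(m.sum(axis=-1), 1.0, atol=1e-5)

    def test_forward_never_nonfinite_across_seeds(self):
        cfg = tiny_config()
        for seed in range(8):
            rng = np.random.default_rng(seed)
            model = EPINTLM(cfg, random_table(rng, dim=cfg.embed_dim), seed=seed)
            toks_e = rng.integers(0, 4097, (2, 60))
            toks_p = rng.integers(0, 4097, (2, 40))
            g = rng.normal(size=(2, 10)).astype(np.float32) * 10
            probs, _ = model(toks_e, toks_p, g)
            assert np.isfinite(probs.data).all()

    def test_missing_genomic_features_default_to_zeros(self, tiny_model, tiny_batch):
        toks_e, toks_p, _ = tiny_batch
        p1, _ = tiny_model(toks_e, toks_p)
        p2, _ = tiny_model(toks_e, toks_p, np.zeros((3, 10), dtype=np.float32))
        assert np.allclose(p1.data, p2.data)

    def test_embedding_width_mismatch_errors(self, rng):
        cfg = tiny_config()
        with pytest.raises(ValueError):
            EPINTLM(cfg, random_table(rng, dim=cfg.embed_dim + 1))


class TestAblationsAndAggregation:
    """The three studied variants: full (H+S+C), w/o residual (C alone),
    w/o residual & cross-attention (S alone)."""

    def _aggregates(self, use_residual, use_cross):
        rng = np.random.default_rng(0)
        cfg = tiny_config(use_residual=use_residual,
                          use_cross_attention=use_cross)
        model = EPINTLM(cfg, random_table(rng, dim=cfg.embed_dim), seed=3)
        h = Tensor(rng.normal(size=(2, 4, 8)).astype(np.float32))
        s = Tensor(rng.normal(size=(2, 4, 8)).astype(np.float32))
        c = Tensor(rng.normal(size=(2, 4, 8)).astype(np.float32))
        he, hp = model._aggregate(h, h, s, s, c if use_cross else None,
                                  c if use_cross else None)
        return h.data, s.data, c.data, he.data

    def test_full_model_three_way_sum(self):
        h, s, c, out = self._aggregates(True, True)
        assert np.allclose(out, h + s + c, atol=1e-6)

    def test_without_residual_keeps_cross_only(self):
        h, s, c, out = self._aggregates(False, True)
        assert np.allclose(out, c)

    def test_without_residual_and_cross_keeps_self_only(self):
        h, s, c, out = self._aggregates(False, False)
        assert np.allclose(out, s)

    def test_sum_is_commutative_and_zero_is_identity(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(2, 3, 4))
        zero = Tensor(np.zeros_like(h, dtype=np.float32))
        ht = Tensor(h.astype(np.float32))
        assert np.allclose((ht + zero + zero).data, h, atol=1e-7)

    def test_genomic_branch_is_self_attention_only(self, tiny_model, tiny_batch):
        # G* == S_G: changing cross/residual flags must not affect the
        # genomic path, which the fused layout places at the last position
        probs_full, maps = tiny_model(*tiny_batch, return_attention=True)
        assert "self_G" in maps
        assert maps["self_G"].shape[-2:] == (1, 1)


class TestLossAndCheckpoint:
    def test_bce_examples(self):
        p = Tensor(np.array([0.5, 0.5], dtype=np.float32))
        assert np.isclose(float(bce_loss(p, [1, 0]).data), np.log(2), atol=1e-5)
        p = Tensor(np.array([0.9, 0.2], dtype=np.float32))
        expected = -0.5 * (np.log(0.9) + np.log(0.8))
        assert np.isclose(float(bce_loss(p, [1, 0]).data), expected, atol=1e-5)
        p = Tensor(np.array([1 - 1e-7, 1e-7], dtype=np.float32))
        assert float(bce_loss(p, [1, 0]).data) < 1e-5

    def test_zero_weight_classifier_gives_half(self, tiny_model, tiny_batch):
        tiny_model.fc2.weight.data[...] = 0.0
        tiny_model.fc2.bias.data[...] = 0.0
        probs, _ = tiny_model(*tiny_batch)
        assert np.allclose(probs.data, 0.5)

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path,
                                                        tiny_model, tiny_batch):
        tiny_model.eval()
        before, _ = tiny_model(*tiny_batch)
        path = tiny_model.save_checkpoint(tmp_path / "m.ckpt.npz")
        restored = EPINTLM.load_checkpoint(path)
        restored.eval()
        after, _ = restored(*tiny_batch)
        assert np.allclose(before.data, after.data, atol=1e-6)
        assert restored.config == tiny_model.config
        assert restored.embedding_provenance == tiny_model.embedding_provenance


class TestEmbeddingTrainability:
    def test_gradient_flows_iff_trainable(self, tiny_model, tiny_batch):
        toks_e, toks_p, g = tiny_batch
        tiny_model.set_embedding_trainable(False)
        probs, _ = tiny_model(toks_e, toks_p, g)
        loss = bce_loss(probs, [1, 0, 1])
        tiny_model.zero_grad()
        loss.backward()
        assert tiny_model.embedding.grad is None
        tiny_model.set_embedding_trainable(True)
        probs, _ = tiny_model(toks_e, toks_p, g)
        loss = bce_loss(probs, [1, 0, 1])
        tiny_model.zero_grad()
        loss.backward()
        assert tiny_model.embedding.grad is not None
        assert np.any(tiny_model.embedding.grad != 0)
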