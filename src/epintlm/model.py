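"""The EPINTLM network.

Architecture, per modality and in order:

1. **Embedding layer** — token indices are looked up in the k-mer
   embedding table (frozen for the first training epochs, trainable
   afterwards).
2. **Local feature extractor** — 1-D convolution (kernel 40, 64
   channels) → ReLU → max pooling (kernel 20) → batch normalization →
   dropout.  2995 enhancer tokens reduce to L'_E = 147 positions, 1995
   promoter tokens to L'_P = 97.
3. **Regulatory dependency encoder** — two-layer bidirectional GRU with
   32 hidden units per direction, giving d = 64 features per position.
4. **Intra-sequence / intra-epigenomic self-attention** on each of the
   enhancer, promoter and (projected) genomic representations.
5. **Inter-sequence cross-attention** in both directions: enhancer
   queries attending over promoter keys/values and vice versa, with
   independent parameters per direction.
6. **Residual aggregation** — H* = H + S + C for each sequence branch;
   the genomic branch uses G* = S_G alone.
7. **Fusion and classification** — position-axis concatenation
   (147 + 97 + 1 positions at canonical lengths, flat width 15 680 at
   d = 64), then a one-hidden-layer MLP with a sigmoid output.

Ablation switches reproduce the studied variants: with
``use_residual=False`` the sequence aggregate is the cross-attention
output alone; with cross-attention also disabled it is the
self-attention output alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .embeddings import EmbeddingTable
from .tokenization import token_count, ENHANCER_LENGTH_BP, PROMOTER_LENGTH_BP


class ModelConfig(BaseModel):
    """All architecture hyperparameters and ablation switches."""

    model_config = ConfigDict(extra="forbid")

    embed_dim: int = 1280
    conv_channels: int = 64
    conv_kernel: int = 40
    pool_kernel: int = 20
    gru_layers: int = 2
    gru_hidden_per_dir: int = 32
    attn_heads: int = 4
    dropout: float = 0.5
    use_residual: bool = True
    use_cross_attention: bool = True
    classifier_hidden: int = 128
    genomic_dim: int = 100
    vocab_size: int = 4097
    enhancer_tokens: int = token_count(ENHANCER_LENGTH_BP)
    promoter_tokens: int = token_count(PROMOTER_LENGTH_BP)

    @property
    def model_dim(self) -> int:
        """d = 2 x GRU hidden size per direction."""
        return 2 * self.gru_hidden_per_dir

    @model_validator(mode="after")
    def _check(self):
        if self.model_dim % self.attn_heads:
            raise ValueError(
                f"attn_heads={self.attn_heads} must divide model_dim={self.model_dim}")
        return self

    def pooled_length(self, tokens: int) -> int:
        """L' = floor((L - K + 1) / P) for valid conv + non-overlapping pool."""
        return (tokens - self.conv_kernel + 1) // self.pool_kernel

    @property
    def fused_flat_width(self) -> int:
        le = self.pooled_length(self.enhancer_tokens)
        lp = self.pooled_length(self.promoter_tokens)
        return (le + lp + 1) * self.model_dim


def reduced_config(**overrides) -> ModelConfig:
    """A desk-scale variant of the architecture: identical wiring and
    canonical sequence geometry, narrower widths.  Used for CPU-sized
    experiments on synthetic data."""
    base = dict(embed_dim=16, conv_channels=16, gru_hidden_per_dir=16,
                attn_heads=2, dropout=0.5, classifier_hidden=32)
    base.update(overrides)
    return ModelConfig(**base)


class _SequenceBranch(nn.Module):
    """Local feature extractor + regulatory dependency encoder for one element."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.conv = nn.Conv1d(cfg.embed_dim, cfg.conv_channels, cfg.conv_kernel, rng)
        self.bn = nn.BatchNorm1d(cfg.conv_channels)
        self.drop = nn.Dropout(cfg.dropout, dropout_rng)
        self.gru = nn.BiGRU(cfg.conv_channels, cfg.gru_hidden_per_dir,
                            cfg.gru_layers, rng)

    def local_features(self, x: Tensor) -> Tensor:
        # conv -> ReLU -> maxpool -> batchnorm -> dropout, in that order
        c = ag.relu(self.conv(x))
        c = ag.maxpool1d(c, self.cfg.pool_kernel)
        c = self.bn(c)
        return self.drop(c)

    def __call__(self, x: Tensor) -> Tensor:
        return self.gru(self.local_features(x))


class EPINTLM(nn.Module):
    """Dual-attention enhancer-promoter interaction classifier.

    Parameters
    ----------
    config
        Architecture hyperparameters.
    embedding_table
        The k-mer lookup table used to initialize the embedding layer;
        its width must match ``config.embed_dim``.
    seed
        Seeds parameter initialization and dropout.
    """

    def __init__(self, config: ModelConfig, embedding_table: EmbeddingTable,
                 seed: int = 0):
        nn.Module.__init__(self)
        if embedding_table.dim != config.embed_dim:
            raise ValueError(
                f"embedding table width {embedding_table.dim} != "
                f"config.embed_dim {config.embed_dim}")
        if embedding_table.vocab_size != config.vocab_size:
            raise ValueError("embedding table vocabulary size mismatch")
        self.config = config
        self.embedding_provenance = embedding_table.provenance
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x45504931]))
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0x45504932]))

        self.embedding = nn.parameter(embedding_table.matrix.copy(), "embedding")
        self.embedding.requires_grad = False  # frozen until the schedule unfreezes

        d = config.model_dim
        self.enh_branch = _SequenceBranch(config, rng, self.dropout_rng)
        self.pro_branch = _SequenceBranch(config, rng, self.dropout_rng)
        self.genomic_proj = nn.Dense(config.genomic_dim, d, rng)
        self.self_attn_e = nn.MultiHeadAttention(d, config.attn_heads, rng)
        self.self_attn_p = nn.MultiHeadAttention(d, config.attn_heads, rng)
        self.self_attn_g = nn.MultiHeadAttention(d, config.attn_heads, rng)
        self.cross_ep = nn.MultiHeadAttention(d, config.attn_heads, rng)
        self.cross_pe = nn.MultiHeadAttention(d, config.attn_heads, rng)
        self.fc1 = nn.Dense(config.fused_flat_width, config.classifier_hidden, rng)
        self.fc_drop = nn.Dropout(config.dropout, self.dropout_rng)
        self.fc2 = nn.Dense(config.classifier_hidden, 1, rng)

    # -- embedding freeze/unfreeze ---------------------------------------
    def set_embedding_trainable(self, trainable: bool) -> None:
        self.embedding.requires_grad = bool(trainable)

    @property
    def embedding_trainable(self) -> bool:
        return self.embedding.requires_grad

    def parameters(self):
        params = super().parameters()
        if "embedding" not in self._params:
            params.append(self.embedding)
        return params

    # -- forward ----------------------------------------------------------
    def forward(self, tokens_e: np.ndarray, tokens_p: np.ndarray,
                genomic: Optional[np.ndarray] = None,
                return_attention: bool = False):
        """Compute interaction probabilities for a batch.

        Parameters
        ----------
        tokens_e, tokens_p
            Integer token matrices, shapes (B, L_E) and (B, L_P).
        genomic
            Raw genomic feature matrix (B, g); zeros when absent.
        return_attention
            Also return the attention maps (numpy, time-major per-head
            weights) for interpretation.

        Returns
        -------
        probs : Tensor, shape (B,)
        aux : dict
            With ``return_attention``: per-direction attention maps of
            shape (H, B, L_q, L_k) under keys ``self_E``, ``self_P``,
            ``self_G``, ``enh_to_pro``, ``pro_to_enh``.
        """
        B = tokens_e.shape[0]
        if genomic is None:
            genomic = np.zeros((B, self.config.genomic_dim), dtype=np.float32)
        genomic = np.asarray(genomic, dtype=np.float32)

        x_e = ag.embedding(self.embedding, tokens_e)   # (B, L_E, d_emb)
        x_p = ag.embedding(self.embedding, tokens_p)
        h_e = self.enh_branch(x_e)                     # (B, L'_E, d)
        h_p = self.pro_branch(x_p)                     # (B, L'_P, d)
        g = ag.reshape(self.genomic_proj(Tensor(genomic)), (B, 1, -1))

        s_e, w_se = self.self_attn_e(h_e)
        s_p, w_sp = self.self_attn_p(h_p)
        s_g, w_sg = self.self_attn_g(g)

        cfg = self.config
        maps = {}
        c_e = c_p = None
        if cfg.use_cross_attention:
            c_e, w_ep = self.cross_ep(h_e, h_p)
            c_p, w_pe = self.cross_pe(h_p, h_e)
            if return_attention:
                maps["enh_to_pro"] = w_ep.transpose(1, 0, 2, 3)
                maps["pro_to_enh"] = w_pe.transpose(1, 0, 2, 3)
        if return_attention:
            maps["self_E"] = w_se.transpose(1, 0, 2, 3)
            maps["self_P"] = w_sp.transpose(1, 0, 2, 3)
            maps["self_G"] = w_sg.transpose(1, 0, 2, 3)

        h_e_star, h_p_star = self._aggregate(h_e, h_p, s_e, s_p,
                                             c_e if cfg.use_cross_attention else None,
                                             c_p if cfg.use_cross_attention else None)
        g_star = s_g  # no residual, no cross term on the genomic branch

        fused = ag.concat([h_e_star, h_p_star, g_star], axis=1)   # (B, LE'+LP'+1, d)
        flat = ag.reshape(fused, (B, -1))
        hidden = self.fc_drop(ag.relu(self.fc1(flat)))
        logits = ag.reshape(self.fc2(hidden), (B,))
        probs = ag.sigmoid(logits)
        return probs, maps

    def _aggregate(self, h_e, h_p, s_e, s_p, c_e, c_p):
        cfg = self.config
        if cfg.use_residual and cfg.use_cross_attention:
            return h_e + s_e + c_e, h_p + s_p + c_p
        if cfg.use_residual and not cfg.use_cross_attention:
            return h_e + s_e, h_p + s_p
        if not cfg.use_residual and cfg.use_cross_attention:
            return c_e, c_p   # "w/o residual": cross-attention output alone
        return s_e, s_p       # "w/o residual & cross-attention"

    __call__ = forward

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, path: str | Path, extra: dict | None = None) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        named = self.named_parameters()
        named["embedding"] = self.embedding
        arrays = {f"param::{k}": v.data for k, v in named.items()}
        for name, child in _iter_batchnorms(self):
            arrays[f"bnstat::{name}.mean"] = child.running_mean
            arrays[f"bnstat::{name}.var"] = child.running_var
        manifest = {
            "container": "epintlm-checkpoint",
            "config": self.config.model_dump(),
            "embedding_provenance": self.embedding_provenance,
            "seed": self.seed,
            "extra": extra or {},
        }
        np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(),
                                              dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "EPINTLM":
        with np.load(Path(path)) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            if manifest.get("container") != "epintlm-checkpoint":
                raise ValueError(f"{path} is not an EPINTLM checkpoint")
            cfg = ModelConfig(**manifest["config"])
            table = EmbeddingTable(
                matrix=z["param::embedding"],
                provenance=manifest["embedding_provenance"])
            model = cls(cfg, table, seed=manifest["seed"])
            named = model.named_parameters()
            for key in z.files:
                if key.startswith("param::"):
                    name = key[len("param::"):]
                    if name == "embedding":
                        continue
                    named[name].data[...] = z[key]
            bns = dict(_iter_batchnorms(model))
            for key in z.files:
                if key.startswith("bnstat::"):
                    name, stat = key[len("bnstat::"):].rsplit(".", 1)
                    setattr(bns[name], f"running_{stat}", z[key].copy())
        return model


def _iter_batchnorms(module: nn.Module, prefix: str = ""):
    for name, child in module._children.items():
        full = prefix + name
        if isinstance(child, nn.BatchNorm1d):
            yield full, child
        yield from _iter_batchnorms(child, full + ".")


def bce_loss(predictions: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Batch-mean binary cross-entropy, with epsilon inside the logs."""
    y = np.asarray(labels, dtype=np.float32)
    p = predictions
    pos = ag.log(p + eps) * Tensor(y)
    neg = ag.log((1.0 - p) + eps) * Tensor(1.0 - y)
    return -(pos + neg).mean()
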