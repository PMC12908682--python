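"""The k-mer embedding lookup table.

Every one of the 4096 possible 6-mers (plus one special token) is
embedded once by a pluggable per-k-mer embedder, and the resulting
``(4097, 1280)`` matrix **E** is used as a plain lookup table: a token
sequence ``I`` of shape ``(B, L)`` embeds to ``E[I]`` of shape
``(B, L, d)``.  The reference embedder is a pretrained DNA language
model (mean-pooled final hidden states per k-mer); the packaged
synthetic embedder (:mod:`epintlm.synthetic`) provides the same
interface with no download.

The table supports a frozen mode (no gradient updates) and a trainable
mode; the training schedule flips the switch between epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .tokenization import KmerVocabulary

#: Embedding width of the reference DNA language model.
DEFAULT_EMBED_DIM = 1280

_CACHE_VERSION = 1


@runtime_checkable
class KmerEmbedder(Protocol):
    """Anything that maps a k-mer string to a fixed-width real vector.

    Implementations must be deterministic for a fixed instance and
    expose ``dim`` (output width) and ``provenance`` (a stable id used
    to key the on-disk cache).
    """

    dim: int
    provenance: str

    def embed(self, kmer: str) -> np.ndarray: ...


def mean_pool(hidden_states: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the leading (position) axis of a T x d matrix."""
    h = np.asarray(hidden_states, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError(f"expected a non-empty T x d matrix, got shape {h.shape}")
    return h.mean(axis=0)


@dataclass
class EmbeddingTable:
    """The (vocab_size x dim) lookup matrix with provenance and a freeze switch."""

    matrix: np.ndarray
    provenance: str
    trainable: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def vocab_size(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def lookup(self, tokens: np.ndarray) -> np.ndarray:
        """Pure-indexing gather: tokens (…,) -> embeddings (…, dim)."""
        idx = np.asarray(tokens)
        if idx.size and (idx.min() < 0 or idx.max() >= self.vocab_size):
            raise IndexError(
                f"token index out of range [0, {self.vocab_size}): "
                f"min={idx.min()}, max={idx.max()}"
            )
        return self.matrix[idx]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        manifest = {
            "container": "epintlm-embedding-table",
            "version": _CACHE_VERSION,
            "provenance": self.provenance,
            "shape": list(self.matrix.shape),
        }
        np.savez(path, matrix=self.matrix, manifest=np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with np.load(Path(path)) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            if manifest.get("container") != "epintlm-embedding-table":
                raise ValueError(f"{path} is not an embedding-table container")
            return cls(matrix=z["matrix"], provenance=manifest["provenance"])


def build_embedding_table(
    embedder: KmerEmbedder,
    vocab: KmerVocabulary | None = None,
    cache_path: str | Path | None = None,
) -> EmbeddingTable:
    """Embed every regular k-mer and assemble the lookup matrix.

    Row ``i`` (for ``i < 4^k``) holds ``embedder.embed(decode(i))``;
    the special-token row is the zero vector (neutral unknown/padding
    semantics).  If ``cache_path`` exists and its provenance tag
    matches the embedder's, the cached table is returned without
    re-embedding; on a tag mismatch the table is rebuilt.
    """
    vocab = vocab or KmerVocabulary()
    if cache_path is not None and Path(cache_path).exists():
        cached = EmbeddingTable.load(cache_path)
        if cached.provenance == embedder.provenance and cached.vocab_size == vocab.size:
            return cached

    dim = embedder.dim
    matrix = np.zeros((vocab.size, dim), dtype=np.float32)
    for i in range(vocab.size - 1):
        kmer = vocab.decode(i)
        vec = np.asarray(embedder.embed(kmer), dtype=np.float32)
        if vec.shape != (dim,):
            raise ValueError(
                f"embedder returned shape {vec.shape} for {kmer!r}, expected ({dim},)"
            )
        if not np.isfinite(vec).all():
            raise ValueError(f"embedder returned non-finite values for k-mer {kmer!r}")
        matrix[i] = vec
    # special-token row stays all-zero
    table = EmbeddingTable(matrix=matrix, provenance=embedder.provenance)
    if cache_path is not None:
        table.save(cache_path)
    return table
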