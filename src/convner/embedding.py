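"""Per-character embeddings: trainable lookup (default) or a pretrained
contextual-embedder adapter, plus the dimension-expansion step applied
before the convolutional stack.

The lookup path is the one the test-suite exercises; the contextual path
is an adapter that consumes locally stored pretrained weights and never
downloads anything.  When no weights are resolvable it raises
:class:`ContextualWeightsUnavailable` telling the caller to use lookup
mode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .convnet import FeatureMap
from .nn import Embedding, Module

__all__ = [
    "EmbeddingSequence", "EmbedderConfig", "LookupEmbedder",
    "ContextualWeightsUnavailable", "StaticContextualEmbedder", "HashEmbedder",
    "embed_lookup", "embed_contextual", "expand_dims", "squeeze",
]


@dataclass
class EmbeddingSequence:
    """L x D embedding matrix with a validity mask over positions."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be L x D")
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask must have length L")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding values")
        if not self.mask.any():
            raise ValueError("mask must have at least one true entry")


@dataclass
class EmbedderConfig:
    mode: str = "lookup"            # {"lookup", "contextual"}
    dim: int = 64                   # 768 is the usual contextual width
    vocab_size: int | None = None   # required in lookup mode
    weights_ref: str | None = None  # local directory with pretrained weights

    def __post_init__(self):
        if self.mode not in ("lookup", "contextual"):
            raise ValueError(f"unknown embedder mode {self.mode!r}")
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.mode == "lookup" and not (self.vocab_size and self.vocab_size > 0):
            raise ValueError("lookup mode requires vocab_size > 0")


class ContextualWeightsUnavailable(RuntimeError):
    pass


class LookupEmbedder(Module):
    """Trainable character-embedding table."""

    def __init__(self, cfg: EmbedderConfig, rng: np.random.Generator):
        if cfg.mode != "lookup":
            raise ValueError("LookupEmbedder requires lookup mode")
        self.cfg = cfg
        self.table = Embedding(cfg.vocab_size, cfg.dim, rng)
        self.dim = cfg.dim

    def __call__(self, indices: np.ndarray) -> Tensor:
        """(B, L) int indices -> (B, L, D) embedding tensor."""
        return self.table(indices)


def embed_lookup(indices, table) -> EmbeddingSequence:
    """Row-select: output row i is table[indices[i]]; shape L x D."""
    tab = table.data if isinstance(table, Tensor) else np.asarray(table, dtype=np.float64)
    idx = np.asarray(indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= tab.shape[0]):
        raise IndexError("embedding index out of range")
    return EmbeddingSequence(tab[idx], np.ones(len(idx), dtype=bool))


class StaticContextualEmbedder:
    """Adapter over locally stored per-character pretrained vectors.

    Expects ``weights_ref`` to be a directory containing ``vocab.txt``
    (one character per line) and ``embeddings.npy`` (|vocab| x D).
    Emits exactly one vector per input character; characters outside the
    stored vocabulary map to the mean vector.
    """

    def __init__(self, vocab: dict[str, int], table: np.ndarray):
        self.vocab = vocab
        self.table = np.asarray(table, dtype=np.float64)
        if self.table.ndim != 2 or len(vocab) != self.table.shape[0]:
            raise ContextualWeightsUnavailable(
                "embedding table does not match vocabulary; "
                "fall back to lookup mode")
        self.dim = self.table.shape[1]
        self._unk = self.table.mean(axis=0)

    @classmethod
    def from_pretrained(cls, weights_ref: str) -> "StaticContextualEmbedder":
        vocab_path = os.path.join(weights_ref, "vocab.txt")
        emb_path = os.path.join(weights_ref, "embeddings.npy")
        if not (os.path.isdir(weights_ref) and os.path.isfile(vocab_path)
                and os.path.isfile(emb_path)):
            raise ContextualWeightsUnavailable(
                f"no pretrained weights at {weights_ref!r}; use the lookup "
                "embedder (EmbedderConfig(mode='lookup')) instead")
        with open(vocab_path, encoding="utf-8") as fh:
            chars = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        table = np.load(emb_path)
        return cls({c: i for i, c in enumerate(chars)}, table)

    def embed(self, chars) -> np.ndarray:
        rows = [self.table[self.vocab[c]] if c in self.vocab else self._unk
                for c in chars]
        return np.stack(rows) if rows else np.zeros((0, self.dim))


class HashEmbedder:
    """Deterministic stand-in embedder (synthetic): each character's
    vector is drawn from an RNG seeded by its codepoint.  Useful as a
    fallback stub when no pretrained weights are on disk."""

    def __init__(self, dim: int = 64):
        self.dim = dim

    def embed(self, chars) -> np.ndarray:
        rows = [np.random.default_rng(ord(c[0]) % (2 ** 31)).standard_normal(self.dim)
                for c in chars]
        return np.stack(rows) if rows else np.zeros((0, self.dim))


def embed_contextual(chars, cfg: EmbedderConfig,
                     embedder=None) -> EmbeddingSequence:
    """One pretrained vector per input character (specials stripped).

    `embedder` may be any object with ``.embed(chars) -> (L, D)``; when
    omitted, weights are loaded from ``cfg.weights_ref``.
    """
    if cfg.mode != "contextual":
        raise ValueError("embed_contextual requires contextual mode")
    if embedder is None:
        if cfg.weights_ref is None:
            raise ContextualWeightsUnavailable(
                "no weights_ref configured; use the lookup embedder instead")
        embedder = StaticContextualEmbedder.from_pretrained(cfg.weights_ref)
    values = np.asarray(embedder.embed(chars), dtype=np.float64)
    if values.shape[0] != len(chars):
        raise ValueError(
            f"alignment error: {len(chars)} characters but {values.shape[0]} vectors")
    return EmbeddingSequence(values, np.ones(len(chars), dtype=bool))


def expand_dims(e: EmbeddingSequence) -> FeatureMap:
    """Add a singleton leading spatial axis: (L, D) -> (1, L, D).

    The sequence becomes an image-like map of height 1 and width L, so
    2-D convolutional operators act as 1-D sequence convolutions.
    Values are unchanged; :func:`squeeze` inverts exactly.
    """
    return FeatureMap(e.values[np.newaxis, :, :], e.mask.copy())


def squeeze(fm: FeatureMap) -> EmbeddingSequence:
    """Inverse of :func:`expand_dims`."""
    v = fm.values
    if v.ndim != 3 or v.shape[0] != 1:
        raise ValueError("expected a height-1 (1, L, D) feature map")
    return EmbeddingSequence(v[0], fm.mask.copy())
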