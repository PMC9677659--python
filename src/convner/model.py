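"""Model assembly: the five architecture variants.

    conv-crf                    embeddings -> conv encoder -> CRF
    bilstm-crf                  embeddings -> BiLSTM -> CRF
    conv-bilstm-crf             embeddings -> conv encoder -> BiLSTM -> CRF
    contextual-conv-crf         pretrained embeddings -> conv encoder -> CRF
    contextual-conv-bilstm-crf  pretrained embeddings -> conv encoder -> BiLSTM -> CRF

The contextual variants consume a frozen pretrained character embedder
through the adapter in :mod:`convner.embedding`; the lookup variants
train their own table.  A single affine map projects the last encoder's
output to the K per-label emission scores consumed by the CRF.
Dropout (parameterised by keep-probability) is applied to the embedding
output and to the final encoder output during training.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .bilstm import BiLSTM
from .convnet import ConvEncoder, ConvStageConfig
from .corpus import LabelScheme, TaggedSentence, Vocab
from .crf import CRF
from .embedding import (ContextualWeightsUnavailable, EmbedderConfig,
                        LookupEmbedder, StaticContextualEmbedder)
from .nn import Dropout, Linear, Module

__all__ = ["VARIANTS", "NERModel", "build_model"]

VARIANTS = ("conv-crf", "bilstm-crf", "conv-bilstm-crf",
            "contextual-conv-crf", "contextual-conv-bilstm-crf")


class NERModel(Module):
    def __init__(self, variant: str, scheme: LabelScheme,
                 embedder_cfg: EmbedderConfig,
                 conv_cfg: ConvStageConfig | None,
                 lstm_dim: int,
                 rng: np.random.Generator,
                 dropout_keep: float = 0.5,
                 contextual_embedder=None):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
        self.variant = variant
        self.scheme = scheme
        self.has_conv = "conv" in variant.split("-")
        self.has_bilstm = "bilstm" in variant.split("-")
        self.contextual = variant.startswith("contextual")

        if self.contextual:
            if contextual_embedder is None:
                if embedder_cfg.weights_ref is None:
                    raise ContextualWeightsUnavailable(
                        "contextual variant needs pretrained weights; configure "
                        "weights_ref or use a lookup variant")
                contextual_embedder = StaticContextualEmbedder.from_pretrained(
                    embedder_cfg.weights_ref)
            self.embedder = contextual_embedder  # frozen, not a Module
            embed_dim = contextual_embedder.dim
        else:
            self.embedder = LookupEmbedder(embedder_cfg, rng)
            embed_dim = embedder_cfg.dim

        width = embed_dim
        if self.has_conv:
            self.conv = ConvEncoder(width, conv_cfg or ConvStageConfig(), rng)
            width = self.conv.cfg.out_channels
        else:
            self.conv = None
        if self.has_bilstm:
            self.bilstm = BiLSTM(width, lstm_dim, rng)
            width = 2 * lstm_dim
        else:
            self.bilstm = None
        self.emission = Linear(width, scheme.n_labels, rng)
        self.crf = CRF(scheme.n_labels, rng, scheme=scheme)
        self.dropout = Dropout(dropout_keep)

    # -- forward --------------------------------------------------------
    def _embed(self, batch, mask: np.ndarray) -> Tensor:
        if self.contextual:
            L = mask.shape[1]
            rows = []
            for chars in batch:  # batch of character tuples
                v = self.embedder.embed(chars)
                pad = np.zeros((L - len(chars), self.embedder.dim))
                rows.append(np.vstack([v, pad]) if len(chars) < L else v)
            return Tensor(np.stack(rows))
        return self.embedder(batch)  # batch of padded index arrays

    def emissions(self, batch, mask: np.ndarray,
                  train_rng: np.random.Generator | None = None) -> Tensor:
        """(B, L, K) emission scores.  `train_rng` enables dropout."""
        h = self._embed(batch, mask)
        h = self.dropout(h, train_rng)
        m = Tensor(np.asarray(mask, dtype=np.float64)[:, :, None])
        h = h * m
        if self.conv is not None:
            h = self.conv(h, mask)
        if self.bilstm is not None:
            h = self.bilstm(h, mask)
        h = self.dropout(h, train_rng)
        return self.emission(h) * m

    def loss(self, batch, labels: np.ndarray, mask: np.ndarray,
             train_rng: np.random.Generator | None = None) -> Tensor:
        e = self.emissions(batch, mask, train_rng)
        return self.crf.nll(e, labels, mask)

    def predict(self, batch, mask: np.ndarray) -> list[list[str]]:
        """Decoded label strings per sentence (hard BIO mask applied)."""
        e = self.emissions(batch, mask).data
        paths = self.crf.decode(e, mask)
        return [[self.scheme.labels[i] for i in p] for p in paths]

    def predict_sentence(self, s: TaggedSentence | list[str], vocab: Vocab) -> list[str]:
        chars = s.chars if isinstance(s, TaggedSentence) else list(s)
        mask = np.ones((1, len(chars)), dtype=bool)
        if self.contextual:
            return self.predict([tuple(chars)], mask)[0]
        idx = vocab.encode(chars)[None, :]
        return self.predict(idx, mask)[0]


def build_model(variant: str, scheme: LabelScheme,
                embedder_cfg: EmbedderConfig | None = None,
                conv_cfg: ConvStageConfig | None = None,
                lstm_dim: int = 256,
                seed: int = 0,
                dropout_keep: float = 0.5,
                contextual_embedder=None) -> NERModel:
    """Construct one of the five variants with seeded initialisation."""
    rng = np.random.default_rng(seed)
    if embedder_cfg is None:
        embedder_cfg = EmbedderConfig(mode="lookup", dim=64, vocab_size=1)
    return NERModel(variant, scheme, embedder_cfg, conv_cfg, lstm_dim, rng,
                    dropout_keep=dropout_keep,
                    contextual_embedder=contextual_embedder)
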