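"""Training loop and model evaluation driver.

Defaults follow the reference training regime: lstm_dim 256, batch size
16, 60 epochs, dropout keep-probability 0.5, Adam at learning rate
0.001.  The loss is the CRF negative log-likelihood.  Gradient-norm
clipping at 5.0 keeps early CRF updates stable.  Runs are deterministic
for a fixed seed in single-thread mode: one numpy Generator drives
shuffling and dropout, and the best-on-validation-F1 parameters are
restored at the end (no early stopping by default; an optional
``stop_f1`` threshold ends training once validation F1 reaches it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import CorpusSplit, LabelScheme, TaggedSentence, Vocab, encode_sentence
from .evaluation import EvalReport, evaluate
from .model import NERModel
from .nn import Adam, clip_grad_norm

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate_model",
           "save_checkpoint", "load_checkpoint_arrays"]

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    lstm_dim: int = 256
    batch_size: int = 16
    epochs: int = 60
    dropout_keep: float = 0.5
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    model_variant: str = "conv-bilstm-crf"
    grad_clip: float = 5.0
    stop_f1: float | None = None  # optional: end once validation F1 reaches this

    def __post_init__(self):
        if min(self.lstm_dim, self.batch_size, self.epochs) <= 0:
            raise ValueError("lstm_dim, batch_size and epochs must be positive")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment (adam) optimizer is supported")


@dataclass
class TrainResult:
    model: NERModel
    losses: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def trace_table(self) -> str:
        """Columnar epoch/loss/validation-F1 trace (for loss-curve plots)."""
        lines = ["epoch\tloss\tval_f1"]
        for i, (l, f) in enumerate(zip(self.losses, self.val_f1), start=1):
            lines.append(f"{i}\t{l:.6f}\t{f:.4f}")
        return "\n".join(lines)


def _encode_corpus(sentences: list[TaggedSentence], scheme: LabelScheme,
                   vocab: Vocab):
    enc = [encode_sentence(s, scheme, vocab) for s in sentences]
    return [c for c, _ in enc], [l for _, l in enc]


def _pad_batch(char_seqs, label_seqs):
    B = len(char_seqs)
    L = max(len(c) for c in char_seqs)
    chars = np.full((B, L), Vocab.PAD, dtype=np.int64)
    labels = np.zeros((B, L), dtype=np.int64)
    mask = np.zeros((B, L), dtype=bool)
    for i, (c, l) in enumerate(zip(char_seqs, label_seqs)):
        chars[i, :len(c)] = c
        labels[i, :len(l)] = l
        mask[i, :len(c)] = True
    return chars, labels, mask


def evaluate_model(model: NERModel, sentences: list[TaggedSentence],
                   vocab: Vocab, batch_size: int = 32) -> EvalReport:
    """Decode `sentences` and score them entity-wise against their gold labels."""
    preds: list[list[str]] = []
    scheme = model.scheme
    chars_all, labels_all = _encode_corpus(sentences, scheme, vocab)
    for i in range(0, len(sentences), batch_size):
        cs = chars_all[i:i + batch_size]
        ls = labels_all[i:i + batch_size]
        chars, _, mask = _pad_batch(cs, ls)
        batch = ([s.chars for s in sentences[i:i + batch_size]]
                 if model.contextual else chars)
        preds.extend(model.predict(batch, mask))
    return evaluate(preds, [list(s.labels) for s in sentences], scheme)


def train(model: NERModel, split: CorpusSplit, cfg: TrainConfig,
          vocab: Vocab, log=None) -> TrainResult:
    """Train `model` on the split's train fold, tracking validation F1.

    Returns the per-epoch loss/F1 trace with the best-validation
    parameters restored into the model.  Raises on non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    scheme = model.scheme
    chars_all, labels_all = _encode_corpus(split.train, scheme, vocab)
    n = len(chars_all)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    result = TrainResult(model)
    best_f1 = -1.0
    best_state: list[np.ndarray] | None = None

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            cs = [chars_all[i] for i in idx]
            ls = [labels_all[i] for i in idx]
            chars, labels, mask = _pad_batch(cs, ls)
            batch = ([split.train[i].chars for i in idx]
                     if model.contextual else chars)
            model.zero_grad()
            loss = model.loss(batch, labels, mask, train_rng=rng)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(
                    f"training diverged: non-finite loss {val} at epoch {epoch}")
            loss.backward()
            clip_grad_norm(opt.params, cfg.grad_clip)
            opt.step()
            epoch_losses.append(val)
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else 0.0
        f1 = (evaluate_model(model, split.validation, vocab).overall.f1 / 100.0
              if split.validation else 0.0)
        result.losses.append(mean_loss)
        result.val_f1.append(f1)
        if log is not None:
            log(f"epoch={epoch} loss={mean_loss:.4f} val_f1={f1:.4f}")
        if f1 > best_f1:
            best_f1 = f1
            best_state = [a.copy() for a in model.state_arrays()]
            result.best_epoch = epoch
        if cfg.stop_f1 is not None and f1 >= cfg.stop_f1:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return result


def save_checkpoint(model: NERModel, vocab: Vocab, cfg: TrainConfig, path):
    """Versioned checkpoint: parameter arrays + vocabulary + config."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "variant": model.variant,
        "entity_types": list(model.scheme.entity_types),
        "vocab": vocab.itos,
        "config": {k: v for k, v in vars(cfg).items()},
        "embed_dim": model.embedder.dim,
        "conv": (None if model.conv is None else {
            "depths": list(model.conv.cfg.depths),
            "channels": list(model.conv.cfg.channels),
            "stem_kernel": model.conv.cfg.stem_kernel,
            "block_dw_kernel": model.conv.cfg.block_dw_kernel,
            "expansion": model.conv.cfg.expansion,
            "downsample_kernel": model.conv.cfg.downsample_kernel,
            "ln_eps": model.conv.cfg.ln_eps,
        }),
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint_arrays(path) -> tuple[dict, list[np.ndarray]]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    return meta, arrays
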