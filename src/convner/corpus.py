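"""BIO-tagged character corpora: label schemes, reading, writing, splitting.

The on-disk dialect is CoNLL-style: one UTF-8 character per line as
``char<space>label``, sentences separated by a blank line.  A character
equal to the separator cannot be represented and is rejected on write.

Two label schemes ship as module-level constants: ``YIDU_SCHEME`` (six
clinical entity types -> 13 BIO labels) and ``WISDOM_TEETH_SCHEME``
(seven types -> 15 labels), matching the two Chinese electronic-medical-
record corpora this model family is used on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelScheme", "TaggedSentence", "CorpusSplit", "Vocab",
    "build_label_scheme", "read_bio_corpus", "write_bio_corpus",
    "split_corpus", "encode_sentence", "decode_labels",
    "YIDU_SCHEME", "WISDOM_TEETH_SCHEME",
]

SEPARATOR = " "


class SchemeViolation(ValueError):
    """A label outside the scheme, or an illegal BIO transition."""


@dataclass(frozen=True)
class LabelScheme:
    """Entity types and the derived BIO label inventory.

    Labels are ordered ``["O", "B-t1", "I-t1", "B-t2", ...]``; indices are
    positions in that list, so index 0 is always "O".
    """

    entity_types: tuple[str, ...]
    labels: tuple[str, ...] = field(init=False)
    label_to_index: dict[str, int] = field(init=False)

    def __post_init__(self):
        labels = ["O"]
        for t in self.entity_types:
            labels += [f"B-{t}", f"I-{t}"]
        object.__setattr__(self, "labels", tuple(labels))
        object.__setattr__(self, "label_to_index",
                           {lab: i for i, lab in enumerate(labels)})

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.label_to_index[label]
        except KeyError:
            raise SchemeViolation(f"unknown label {label!r}") from None

    def is_legal_transition(self, prev: str | None, curr: str) -> bool:
        """BIO legality: "I-x" may only follow "B-x" or "I-x".

        ``prev=None`` denotes sentence start.  Total over label pairs:
        any pair not of the restricted I-continuation form is legal.
        """
        if not curr.startswith("I-"):
            return True
        if prev is None:
            return False
        return prev == f"B-{curr[2:]}" or prev == f"I-{curr[2:]}"

    def validate_labels(self, labels: list[str] | tuple[str, ...]):
        prev = None
        for i, lab in enumerate(labels):
            if lab not in self.label_to_index:
                raise SchemeViolation(f"unknown label {lab!r} at position {i}")
            if not self.is_legal_transition(prev, lab):
                raise SchemeViolation(
                    f"illegal BIO transition {prev!r} -> {lab!r} at position {i}")
            prev = lab

    def transition_legality(self) -> np.ndarray:
        """(K, K) boolean matrix: allowed[i, j] iff label j may follow label i."""
        K = self.n_labels
        allowed = np.ones((K, K), dtype=bool)
        for j, lab_j in enumerate(self.labels):
            for i, lab_i in enumerate(self.labels):
                allowed[i, j] = self.is_legal_transition(lab_i, lab_j)
        return allowed

    def start_legality(self) -> np.ndarray:
        """Length-K boolean vector: labels allowed at sentence start."""
        return np.array([self.is_legal_transition(None, lab) for lab in self.labels])


def build_label_scheme(entity_types: list[str]) -> LabelScheme:
    """Build a BIO scheme; label count is 2 * len(entity_types) + 1."""
    if not entity_types:
        raise ValueError("entity_types must be nonempty")
    if len(set(entity_types)) != len(entity_types):
        raise ValueError("duplicate entity type names")
    if any(not t for t in entity_types):
        raise ValueError("empty entity type name")
    return LabelScheme(tuple(entity_types))


YIDU_SCHEME = build_label_scheme(
    ["disease", "position", "LabCheck", "check", "drug", "method"])
WISDOM_TEETH_SCHEME = build_label_scheme(
    ["disease", "symptom", "age", "history", "check", "method", "drug"])


@dataclass(frozen=True)
class TaggedSentence:
    chars: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.chars) != len(self.labels):
            raise ValueError("chars and labels must have equal length")

    def __len__(self):
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)


@dataclass(frozen=True)
class CorpusSplit:
    train: list[TaggedSentence]
    validation: list[TaggedSentence]
    test: list[TaggedSentence]
    seed: int


def read_bio_corpus(path, scheme: LabelScheme) -> list[TaggedSentence]:
    """Parse a CoNLL-style BIO file, validating every label against `scheme`."""
    sentences: list[TaggedSentence] = []
    chars: list[str] = []
    labels: list[str] = []

    def flush(lineno):
        nonlocal chars, labels
        if not chars:
            return
        try:
            scheme.validate_labels(labels)
        except SchemeViolation as e:
            raise SchemeViolation(f"{path}: sentence ending at line {lineno}: {e}") from None
        sentences.append(TaggedSentence(tuple(chars), tuple(labels)))
        chars, labels = [], []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            parts = line.split(SEPARATOR)
            if len(parts) != 2 or not parts[0]:
                raise SchemeViolation(f"{path}:{lineno}: malformed line {line!r}")
            ch, lab = parts
            if lab not in scheme.label_to_index:
                raise SchemeViolation(f"{path}:{lineno}: unknown label {lab!r}")
            chars.append(ch)
            labels.append(lab)
        flush(lineno)
    return sentences


def write_bio_corpus(sentences: list[TaggedSentence], path) -> None:
    """Write sentences in the CoNLL dialect; round-trips with read_bio_corpus."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            if len(s) == 0:
                warnings.warn("skipping length-0 sentence on write")
                continue
            for ch, lab in zip(s.chars, s.labels):
                if SEPARATOR in ch:
                    raise ValueError(
                        f"character {ch!r} equals the column separator and cannot "
                        "be represented in this dialect")
                fh.write(f"{ch}{SEPARATOR}{lab}\n")
            fh.write("\n")


def split_corpus(sentences: list[TaggedSentence],
                 ratio: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 seed: int = 0) -> CorpusSplit:
    """Random sentence-level partition into train/validation/test.

    Deterministic for a given (sentences, ratio, seed).  Sizes are the
    rounded proportions; the test fold absorbs rounding remainders.
    """
    if len(sentences) < 3:
        raise ValueError("need at least 3 sentences to split")
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0) or r.sum() <= 0:
        raise ValueError("ratio entries must be nonnegative with positive sum")
    r = r / r.sum()
    n = len(sentences)
    n_train = int(round(n * r[0]))
    n_val = int(round(n * r[1]))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    order = np.random.default_rng(seed).permutation(n)
    train = [sentences[i] for i in order[:n_train]]
    val = [sentences[i] for i in order[n_train:n_train + n_val]]
    test = [sentences[i] for i in order[n_train + n_val:]]
    return CorpusSplit(train, val, test, seed)


class Vocab:
    """Character <-> index map with a reserved unknown index 0 and pad index 1."""

    UNK, PAD = 0, 1

    def __init__(self, chars: list[str]):
        self.itos = ["<unk>", "<pad>"] + list(dict.fromkeys(chars))
        self.stoi = {c: i for i, c in enumerate(self.itos)}

    @classmethod
    def from_sentences(cls, sentences: list[TaggedSentence]) -> "Vocab":
        return cls([c for s in sentences for c in s.chars])

    def __len__(self):
        return len(self.itos)

    def encode(self, chars) -> np.ndarray:
        return np.array([self.stoi.get(c, self.UNK) for c in chars], dtype=np.int64)


def encode_sentence(s: TaggedSentence, scheme: LabelScheme,
                    vocab: Vocab) -> tuple[np.ndarray, np.ndarray]:
    """Map characters and labels to integer index sequences (lengths preserved)."""
    char_idx = vocab.encode(s.chars)
    lab_idx = np.array([scheme.index(lab) for lab in s.labels], dtype=np.int64)
    return char_idx, lab_idx


def decode_labels(indices, scheme: LabelScheme) -> list[str]:
    return [scheme.labels[int(i)] for i in indices]


def cap_sentence_length(sentences: list[TaggedSentence],
                        max_len: int = 256) -> list[TaggedSentence]:
    """Split sentences longer than `max_len` at the last "O" before the cap.

    If no "O" occurs before the cap the sentence is split hard at the cap
    boundary closest to it that keeps BIO legality (i.e. never inside an
    entity unless the entity itself exceeds the cap).
    """
    out: list[TaggedSentence] = []
    for s in sentences:
        chars, labels = list(s.chars), list(s.labels)
        while len(chars) > max_len:
            cut = max_len
            for j in range(max_len - 1, -1, -1):
                if labels[j] == "O":
                    cut = j + 1
                    break
            out.append(TaggedSentence(tuple(chars[:cut]), tuple(labels[:cut])))
            chars, labels = chars[cut:], labels[cut:]
            # a fragment starting with I-x is repaired to B-x to stay legal
            if labels and labels[0].startswith("I-"):
                labels[0] = "B-" + labels[0][2:]
        if chars:
            out.append(TaggedSentence(tuple(chars), tuple(labels)))
    return out
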