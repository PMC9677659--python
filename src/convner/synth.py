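"""Synthetic BIO corpus generation.

Builds character corpora that mimic the shape of clinical NER data —
sentences of CJK characters with embedded multi-character entity
mentions — with controllable entity statistics, so the whole
encode/train/decode/evaluate pipeline can be exercised offline.

The default regime: filler characters come from a fixed 200-character
CJK block sample that is disjoint from every lexicon character, so
entity membership is learnable from characters alone.  A per-type
character pool makes the entity *type* learnable as well.  An
``overlap`` knob mixes filler characters into the lexicon pools to
harden the task.  This emulates the statistical shape of an annotated
medical corpus, not clinical language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .corpus import LabelScheme, TaggedSentence

__all__ = [
    "EntityLexicon", "GeneratorConfig", "default_filler_alphabet",
    "default_lexicon", "generate_sentence", "generate_corpus", "load_lexicon",
]

_CJK_START = 0x4E00  # start of the unified CJK ideograph block


def default_filler_alphabet(size: int = 200) -> str:
    """A fixed sample of `size` CJK ideographs used as context filler."""
    return "".join(chr(_CJK_START + i) for i in range(size))


@dataclass
class EntityLexicon:
    """Per-type surface strings with sampling weights.

    surfaces[t] is a list of multi-character strings; weights[t] the
    matching positive sampling weights (normalised on use).
    """

    surfaces: dict[str, list[str]]
    weights: dict[str, np.ndarray] = field(default=None)

    def __post_init__(self):
        if self.weights is None:
            self.weights = {t: np.ones(len(ss)) for t, ss in self.surfaces.items()}
        for t, ss in self.surfaces.items():
            if any(len(s) < 1 for s in ss):
                raise ValueError(f"empty surface string for type {t!r}")
            w = np.asarray(self.weights[t], dtype=float)
            if len(w) != len(ss) or np.any(w <= 0):
                raise ValueError(f"bad weights for type {t!r}")
            self.weights[t] = w

    @property
    def types(self) -> list[str]:
        return list(self.surfaces)

    def characters(self) -> set[str]:
        return {c for ss in self.surfaces.values() for s in ss for c in s}


def default_lexicon(scheme: LabelScheme, seed: int = 0,
                    surfaces_per_type: int = 30,
                    length_range: tuple[int, int] = (2, 5),
                    overlap: float = 0.0) -> EntityLexicon:
    """Programmatic lexicon over CJK ideographs, disjoint from the filler.

    Each entity type draws its surfaces from a private 40-character pool
    starting above the filler block, so both entity membership and type
    are decodable from characters.  ``overlap`` in [0, 1] replaces that
    fraction of each pool with filler characters to harden the task.
    """
    rng = np.random.default_rng(seed)
    filler = default_filler_alphabet()
    pool_size = 40
    lo, hi = length_range
    surfaces: dict[str, list[str]] = {}
    for k, t in enumerate(scheme.entity_types):
        base = _CJK_START + 200 + k * pool_size
        pool = [chr(base + i) for i in range(pool_size)]
        if overlap > 0:
            n_swap = int(round(overlap * pool_size))
            swap_idx = rng.choice(pool_size, size=n_swap, replace=False)
            fill_idx = rng.choice(len(filler), size=n_swap, replace=True)
            for si, fi in zip(swap_idx, fill_idx):
                pool[si] = filler[fi]
        seen: set[str] = set()
        words: list[str] = []
        while len(words) < surfaces_per_type:
            n = int(rng.integers(lo, hi + 1))
            w = "".join(rng.choice(pool, size=n))
            if w not in seen:
                seen.add(w)
                words.append(w)
        surfaces[t] = words
    return EntityLexicon(surfaces)


@dataclass
class GeneratorConfig:
    """Knobs of the corpus generator.

    entity_density is the expected number of entity mentions per
    sentence (per-sentence counts are Poisson); type_weights are the
    mixing proportions over entity types (uniform when None).
    """

    scheme: LabelScheme
    n_sentences: int = 2000
    sentence_length: tuple[int, int] = (10, 30)
    entity_density: float = 2.0
    filler_alphabet: str = field(default_factory=default_filler_alphabet)
    type_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.entity_density < 0:
            raise ValueError("entity_density must be >= 0")
        lo, hi = self.sentence_length
        if not (1 <= lo <= hi):
            raise ValueError("sentence_length range must be nonempty and >= 1")
        if not self.filler_alphabet:
            raise ValueError("filler_alphabet must be nonempty")
        if self.type_weights is not None:
            w = np.asarray(self.type_weights, dtype=float)
            if len(w) != len(self.scheme.entity_types) or np.any(w < 0):
                raise ValueError("type_weights must match entity types, nonnegative")
            self.type_weights = w / w.sum()


def _normalized_type_weights(cfg: GeneratorConfig, lexicon: EntityLexicon) -> np.ndarray:
    if cfg.type_weights is not None:
        return cfg.type_weights
    k = len(cfg.scheme.entity_types)
    return np.full(k, 1.0 / k)


def generate_sentence(lexicon: EntityLexicon, cfg: GeneratorConfig,
                      rng: np.random.Generator) -> TaggedSentence:
    """One BIO-legal sentence with non-overlapping embedded entities.

    Entities that do not fit the remaining character budget are
    resampled (then dropped if nothing fits).
    """
    lo, hi = cfg.sentence_length
    L = int(rng.integers(lo, hi + 1))
    types = list(cfg.scheme.entity_types)
    tw = _normalized_type_weights(cfg, lexicon)

    mentions: list[tuple[str, str]] = []  # (type, surface)
    if cfg.entity_density > 0:
        if not lexicon.surfaces or all(not s for s in lexicon.surfaces.values()):
            raise ValueError("entity_density > 0 requires a nonempty lexicon")
        n_target = int(rng.poisson(cfg.entity_density))
        budget = L
        for _ in range(n_target):
            placed = False
            for _attempt in range(20):  # resample entities that exceed the budget
                t = types[int(rng.choice(len(types), p=tw))]
                ss, w = lexicon.surfaces[t], lexicon.weights[t]
                surf = ss[int(rng.choice(len(ss), p=w / w.sum()))]
                if len(surf) <= budget:
                    mentions.append((t, surf))
                    budget -= len(surf)
                    placed = True
                    break
            if not placed:
                break

    n_fill = L - sum(len(s) for _, s in mentions)
    gaps = rng.multinomial(n_fill, np.full(len(mentions) + 1, 1.0 / (len(mentions) + 1)))
    filler = list(cfg.filler_alphabet)

    chars: list[str] = []
    labels: list[str] = []

    def emit_filler(n):
        for _ in range(n):
            chars.append(filler[int(rng.integers(len(filler)))])
            labels.append("O")

    emit_filler(int(gaps[0]))
    for g, (t, surf) in zip(gaps[1:], mentions):
        chars.append(surf[0])
        labels.append(f"B-{t}")
        for c in surf[1:]:
            chars.append(c)
            labels.append(f"I-{t}")
        emit_filler(int(g))
    return TaggedSentence(tuple(chars), tuple(labels))


def generate_corpus(lexicon: EntityLexicon, cfg: GeneratorConfig) -> list[TaggedSentence]:
    """cfg.n_sentences sentences from a single generator seeded with cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.entity_density > 0 and not any(lexicon.surfaces.values()):
        raise ValueError("entity_density > 0 requires a nonempty lexicon")
    return [generate_sentence(lexicon, cfg, rng) for _ in range(cfg.n_sentences)]


def load_lexicon(path) -> EntityLexicon:
    """Load a lexicon config file: mapping entity type -> list of strings."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("lexicon file must map entity types to string lists")
    return EntityLexicon({t: [str(s) for s in ss] for t, ss in raw.items()})
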