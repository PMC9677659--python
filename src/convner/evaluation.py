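"""Entity-level evaluation: precision, recall and F1 over exact
(type, span) matches.

A predicted entity counts as a true positive iff an identical
(type, start, end) span exists in the gold annotation.  Precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 is their harmonic mean
2/F1 = 1/P + 1/R.  Counts are reported per entity type and aggregated
micro-style into a comprehensive value; a zero denominator yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import LabelScheme, TaggedSentence

__all__ = ["Span", "TypeScores", "EvalReport", "extract_entities", "evaluate",
           "prf_from_counts"]

Span = tuple[str, int, int]  # (entity type, start, end) — half-open


def extract_entities(labels) -> set[Span]:
    """Decode BIO labels into entity spans.

    Maximal B-x (I-x)* runs become half-open (x, start, end) spans.  An
    illegal I-continuation (after "O", at sentence start, or after a
    different type) is repaired by starting a new span there.
    """
    spans: set[Span] = set()
    cur_type: str | None = None
    cur_start = 0
    for i, lab in enumerate(labels):
        if lab == "O":
            if cur_type is not None:
                spans.add((cur_type, cur_start, i))
                cur_type = None
        elif lab.startswith("B-"):
            if cur_type is not None:
                spans.add((cur_type, cur_start, i))
            cur_type, cur_start = lab[2:], i
        elif lab.startswith("I-"):
            t = lab[2:]
            if cur_type != t:  # repair: treat as the start of a new entity
                if cur_type is not None:
                    spans.add((cur_type, cur_start, i))
                cur_type, cur_start = t, i
        else:
            raise ValueError(f"not a BIO label: {lab!r}")
    if cur_type is not None:
        spans.add((cur_type, cur_start, len(list(labels))))
    return spans


def prf_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(P, R, F1) percentages from counts; zero denominators give 0."""
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class TypeScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return prf_from_counts(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return prf_from_counts(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return prf_from_counts(self.tp, self.fp, self.fn)[2]


@dataclass
class EvalReport:
    """Per-type and comprehensive (micro-averaged) entity scores."""

    per_type: dict[str, TypeScores] = field(default_factory=dict)

    @property
    def overall(self) -> TypeScores:
        return TypeScores(tp=sum(s.tp for s in self.per_type.values()),
                          fp=sum(s.fp for s in self.per_type.values()),
                          fn=sum(s.fn for s in self.per_type.values()))

    def as_table(self) -> str:
        """Delimited table: one row per entity type plus the
        comprehensive row; P/R/F1 to two decimals."""
        lines = ["type\tTP\tFP\tFN\tP\tR\tF1"]
        for t, s in self.per_type.items():
            lines.append(f"{t}\t{s.tp}\t{s.fp}\t{s.fn}"
                         f"\t{s.precision:.2f}\t{s.recall:.2f}\t{s.f1:.2f}")
        o = self.overall
        lines.append(f"comprehensive\t{o.tp}\t{o.fp}\t{o.fn}"
                     f"\t{o.precision:.2f}\t{o.recall:.2f}\t{o.f1:.2f}")
        return "\n".join(lines)


def evaluate(pred_sentences: list[TaggedSentence] | list[list[str]],
             gold_sentences: list[TaggedSentence] | list[list[str]],
             scheme: LabelScheme) -> EvalReport:
    """Compare aligned predicted and gold label sequences entity-wise."""
    if len(pred_sentences) != len(gold_sentences):
        raise ValueError("prediction and gold corpora differ in length")
    report = EvalReport({t: TypeScores() for t in scheme.entity_types})
    for pred, gold in zip(pred_sentences, gold_sentences):
        p_labels = pred.labels if isinstance(pred, TaggedSentence) else pred
        g_labels = gold.labels if isinstance(gold, TaggedSentence) else gold
        if len(p_labels) != len(g_labels):
            raise ValueError("misaligned sentence lengths")
        p_spans = extract_entities(p_labels)
        g_spans = extract_entities(g_labels)
        for span in p_spans:
            t = span[0]
            report.per_type.setdefault(t, TypeScores())
            if span in g_spans:
                report.per_type[t].tp += 1
            else:
                report.per_type[t].fp += 1
        for span in g_spans - p_spans:
            t = span[0]
            report.per_type.setdefault(t, TypeScores())
            report.per_type[t].fn += 1
    return report
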