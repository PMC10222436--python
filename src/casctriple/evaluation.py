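"""Exact-match triplet scoring and the Normal / EPO / SEO overlap taxonomy.

A predicted triplet counts as a true positive iff its (subject surface,
predicate, object surface) exactly equals a gold triplet, matched one-to-one
(multiset intersection).  Precision, recall and F1 follow the usual
definitions with 0 returned on empty denominators.

Sentences are partitioned by the overlap structure of their gold triplet
sets: EPO (entity pair overlap) if two triplets share the same ordered
(subject, object) pair; else SEO (single entity overlap) if two triplets
share at least one entity; else Normal.  EPO takes precedence over SEO, so
every sentence with at least one triplet receives exactly one class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import AnnotatedSentence, Triplet

NORMAL, EPO, SEO = "Normal", "EPO", "SEO"
CLASSES = (NORMAL, EPO, SEO)


def _keys(triplets: Iterable[Triplet], spans: bool) -> Counter:
    if spans:
        return Counter((t.subject, t.subject_span, t.predicate,
                        t.object, t.object_span) for t in triplets)
    return Counter(t.surfaces() for t in triplets)


def match_triplets(pred: Sequence[Triplet], gold: Sequence[Triplet],
                   spans: bool = False) -> tuple[int, int, int]:
    """(tp, fp, fn) under exact one-to-one matching.

    Duplicate gold triplets are deduplicated before scoring; with
    ``spans=True`` the character spans must match as well as the surfaces.
    """
    pred_keys = _keys(pred, spans)
    gold_keys = _keys(gold, spans)
    gold_keys = Counter(set(gold_keys))          # deduplicate gold
    tp = sum((pred_keys & gold_keys).values())
    fp = sum(pred_keys.values()) - tp
    fn = sum(gold_keys.values()) - tp
    return tp, fp, fn


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1; 0 by convention on empty denominators."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def overlap_class(sentence: AnnotatedSentence) -> str:
    """Classify a sentence by the overlap structure of its gold triplets."""
    triplets = list({t.surfaces() for t in sentence.triplets})
    if not triplets:
        raise ValueError("overlap class undefined for a sentence with no triplets")
    pairs = [(s, o) for s, _, o in triplets]
    if len(pairs) != len(set(pairs)):
        return EPO
    for i in range(len(triplets)):
        si, _, oi = triplets[i]
        for j in range(i + 1, len(triplets)):
            sj, _, oj = triplets[j]
            if {si, oi} & {sj, oj}:
                return SEO
    return NORMAL


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    per_class: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return prf(self.tp, self.fp, self.fn)[2]

    def add(self, tp: int, fp: int, fn: int) -> None:
        self.tp += tp
        self.fp += fp
        self.fn += fn

    def to_dict(self) -> dict:
        d = {"tp": self.tp, "fp": self.fp, "fn": self.fn,
             "precision": self.precision, "recall": self.recall, "f1": self.f1}
        if self.per_class:
            d["per_class"] = {k: v.to_dict() for k, v in self.per_class.items()}
        return d

    def __str__(self) -> str:
        rows = [("overall", self)] + sorted(self.per_class.items())
        lines = [f"{'class':<8} {'TP':>5} {'FP':>5} {'FN':>5} "
                 f"{'prec':>7} {'rec':>7} {'F1':>7}"]
        for name, rep in rows:
            lines.append(f"{name:<8} {rep.tp:>5} {rep.fp:>5} {rep.fn:>5} "
                         f"{rep.precision:>7.3f} {rep.recall:>7.3f} {rep.f1:>7.3f}")
        return "\n".join(lines)


def evaluate(pred_sentences: Sequence[AnnotatedSentence],
             gold_sentences: Sequence[AnnotatedSentence],
             by_class: bool = True, spans: bool = False) -> EvalReport:
    """Corpus-level exact-match report; sentences are matched by position."""
    if len(pred_sentences) != len(gold_sentences):
        raise ValueError("prediction and gold corpora differ in length")
    report = EvalReport()
    if by_class:
        report.per_class = {c: EvalReport() for c in CLASSES}
    for pred, gold in zip(pred_sentences, gold_sentences):
        tp, fp, fn = match_triplets(pred.triplets, gold.triplets, spans=spans)
        report.add(tp, fp, fn)
        if by_class and gold.triplets:
            report.per_class[overlap_class(gold)].add(tp, fp, fn)
    return report
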