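"""Strict entity/relation scoring, inter-annotator agreement, and the
symptom-information-utilization (annotation-rate) metric.

An entity counts as correct only when boundaries *and* type match
exactly; a relation only when both endpoint entities and the relation
type match.  With y1 the reference annotation set and y2 the prediction,

    R  = |y1 ∩ y2| / |y1|,
    P  = |y1 ∩ y2| / |y2|,
    F1 = 2 P R / (P + R),

with the convention P (resp. R) = 0 when y2 (resp. y1) is empty and
F1 = 0 when P + R = 0.  F1 is symmetric under exchanging y1 and y2,
which is why the same formulas serve as pairwise inter-annotator
agreement with one annotator taken as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .schema import (
    AnnotatedDocument,
    SegmentationConfig,
    DEFAULT_SEGMENTATION,
)


@dataclass
class EvalScores:
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_pred: int
    n_correct: int
    per_type: dict[str, "EvalScores"] = field(default_factory=dict)


def prf(n_correct: int, n_gold: int, n_pred: int) -> tuple[float, float, float]:
    p = n_correct / n_pred if n_pred else 0.0
    r = n_correct / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _score(gold_keys: set, pred_keys: set, type_of) -> EvalScores:
    correct = gold_keys & pred_keys
    p, r, f1 = prf(len(correct), len(gold_keys), len(pred_keys))
    per_type: dict[str, EvalScores] = {}
    labels = {type_of(k) for k in gold_keys | pred_keys}
    for label in sorted(labels):
        g = {k for k in gold_keys if type_of(k) == label}
        q = {k for k in pred_keys if type_of(k) == label}
        tp, tr, tf = prf(len(g & q), len(g), len(q))
        per_type[label] = EvalScores(tp, tr, tf, len(g), len(q), len(g & q))
    return EvalScores(p, r, f1, len(gold_keys), len(pred_keys), len(correct), per_type)


def _check_aligned(gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]) -> None:
    gids = [d.doc_id for d in gold]
    pids = [d.doc_id for d in pred]
    if sorted(gids) != sorted(pids):
        raise ValueError(f"corpora carry different doc_ids: {sorted(gids)[:5]}... vs {sorted(pids)[:5]}...")
    if len(set(gids)) != len(gids):
        raise ValueError("duplicate doc_ids in corpus")
    ptext = {d.doc_id: d.text for d in pred}
    for d in gold:
        if ptext[d.doc_id] != d.text:
            raise ValueError(f"document {d.doc_id}: texts differ between corpora")


def _entity_keys(docs: Sequence[AnnotatedDocument]) -> set:
    return {(d.doc_id,) + e.key() for d in docs for e in d.entities}


def _relation_keys(docs: Sequence[AnnotatedDocument]) -> set:
    return {(d.doc_id,) + k for d in docs for k in d.relation_keys()}


def strict_entity_prf(
    gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]
) -> EvalScores:
    """Micro and per-label P/R/F1 over strict entity keys (start, end, label)."""
    _check_aligned(gold, pred)
    return _score(_entity_keys(gold), _entity_keys(pred), type_of=lambda k: k[3])


def strict_relation_prf(
    gold: Sequence[AnnotatedDocument], pred: Sequence[AnnotatedDocument]
) -> EvalScores:
    """Micro and per-label P/R/F1 over strict relation keys
    (subject entity key, object entity key, relation label)."""
    _check_aligned(gold, pred)
    return _score(_relation_keys(gold), _relation_keys(pred), type_of=lambda k: k[3])


def iaa_report(
    a: Sequence[AnnotatedDocument],
    b: Sequence[AnnotatedDocument],
    level: str = "entities",
) -> EvalScores:
    """Pairwise inter-annotator agreement: annotator ``a`` as reference,
    ``b`` as prediction.  F1 is unchanged when a and b are exchanged."""
    if level == "entities":
        return strict_entity_prf(a, b)
    if level == "relations":
        return strict_relation_prf(a, b)
    raise ValueError(f"level must be 'entities' or 'relations', got {level!r}")


def annotation_rate(
    docs: Sequence[AnnotatedDocument],
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> tuple[float, list[tuple[str, int, float]]]:
    """Symptom-information utilization: mean per-sentence fraction of
    characters covered by entity annotations.

    The text is cut into sentence regions (each region runs up to and
    including its terminating delimiter, so delimiters count in the
    denominator).  Returns the corpus mean over all sentences and a
    per-sentence breakdown of (doc_id, sentence index, rate).

    Raises ``ValueError`` on an empty corpus or a corpus without text.
    """
    if not docs:
        raise ValueError("annotation_rate needs at least one document")
    breakdown: list[tuple[str, int, float]] = []
    for doc in docs:
        covered = [False] * len(doc.text)
        for e in doc.entities:
            for i in range(max(e.start, 0), min(e.end, len(doc.text))):
                covered[i] = True
        # region k runs from the previous sentence delimiter (exclusive)
        # through its own delimiter (inclusive)
        bounds = [i + 1 for i, ch in enumerate(doc.text) if ch in cfg.sentence_delims]
        if not bounds or bounds[-1] < len(doc.text):
            bounds.append(len(doc.text))
        lo = 0
        for idx, hi in enumerate(bounds):
            if hi > lo:
                rate = sum(covered[lo:hi]) / (hi - lo)
                breakdown.append((doc.doc_id, idx, rate))
            lo = hi
    if not breakdown:
        raise ValueError("corpus contains no text")
    mean = sum(r for _, _, r in breakdown) / len(breakdown)
    return mean, breakdown
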