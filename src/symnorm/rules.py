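"""Rule-based relation extraction over fine-grained symptom entities.

Five deterministic procedures, each anchored on one entity family:

1. every ``State`` attaches to one position entity — to a neighbouring
   ``Pos_Pri`` when one flanks it, otherwise to the first position
   entity found scanning leftward (``SPri``/``SSub``/``SSCP`` according
   to the position's type);
2. every ``Pos_SCP`` becomes the object of an ``SSCP`` whose subject is
   the first ``Pos_Pri``/``Pos_Sub`` to its right;
3. a ``Neg`` negates every ``State``/``Symp_S`` to its right up to the
   next "，" or "。" (the enumeration mark "、" does not stop the scan);
4. a ``Time`` stamps every ``State``/``Symp_S`` between it and the next
   ``Time`` entity, crossing clause and sentence boundaries;
5. ``Cond``/``Trend``/``Freq``/``Sev_Qual``/``Sev_Quant`` attach to all
   ``State``/``Symp_S`` entities within the same clause.

The scan bounds the published rules leave open are configurable on
:class:`RuleConfig`; defaults keep position attachment within one
sentence (rule 1) and scope attachment within one clause (rule 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .schema import (
    ATTRIBUTE_RELATION,
    ATTRIBUTE_TYPES,
    POSITION_TYPES,
    SYMPTOM_TYPES,
    AnnotatedDocument,
    Entity,
    EntityType,
    Relation,
    RelationType,
    SegmentationConfig,
    has_delim_between,
    clause_spans,
)


@dataclass
class RuleConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    #: rule 1's case-3 leftward scan (and the neighbour test) stops at "。";
    #: shared positions may span clauses but not sentences
    bound_rule1_left_scan_at_sentence: bool = True
    #: rule 2's rightward scan stops at the clause boundary
    rule2_stop_at_clause: bool = True
    #: additionally link each subordinate position to its primary
    #: (gold corpora carry these via progressive annotation; the printed
    #: rules do not generate them, hence off by default)
    chain_subordinate_to_primary: bool = False


DEFAULT_RULES = RuleConfig()

# relations built by the rules before ids are assigned
_PROTO_ID = -1


def _require_label(e: Entity, *labels: EntityType) -> None:
    if e.label not in labels:
        raise ValueError(f"entity {e.id} has label {e.label.value}; expected one of "
                         f"{sorted(l.value for l in labels)}")


def neighbor_entities(
    doc: AnnotatedDocument, e: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> tuple[Optional[Entity], Optional[Entity]]:
    """The entities adjacent to ``e`` in (start, end) order.

    With sentence bounding on (default), a neighbour separated from
    ``e`` by a sentence delimiter is reported as absent.
    """
    ordered = doc.sorted_entities()
    idx = next(i for i, x in enumerate(ordered) if x.id == e.id)
    left = ordered[idx - 1] if idx > 0 else None
    right = ordered[idx + 1] if idx + 1 < len(ordered) else None
    if cfg.bound_rule1_left_scan_at_sentence:
        delims = cfg.segmentation.sentence_delims
        if left is not None and has_delim_between(doc.text, left.end, e.start, delims):
            left = None
        if right is not None and has_delim_between(doc.text, e.end, right.start, delims):
            right = None
    return left, right


_POSITION_RELATION = {
    EntityType.POS_PRI: RelationType.SPRI,
    EntityType.POS_SUB: RelationType.SSUB,
    EntityType.POS_SCP: RelationType.SSCP,
}


def rule1_position_for_state(
    doc: AnnotatedDocument, state: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> Optional[Relation]:
    """Attach a ``State`` to its position entity (at most one relation).

    Case 1: both neighbours are ``Pos_Pri`` -> ``SPri`` with the left one.
    Case 2: the right neighbour is ``Pos_Pri`` and the left is not ->
    ``SPri`` with the right one.  Case 3: otherwise scan leftward
    (crossing "，", stopping at the sentence start when bounding is on)
    for the first position entity and emit the type-matched relation.
    """
    _require_label(state, EntityType.STATE)
    left, right = neighbor_entities(doc, state, cfg)
    left_is_pri = left is not None and left.label is EntityType.POS_PRI
    right_is_pri = right is not None and right.label is EntityType.POS_PRI
    if left_is_pri and right_is_pri:
        target = left
    elif right_is_pri:
        target = right
    else:
        target = None
        delims = (
            cfg.segmentation.sentence_delims
            if cfg.bound_rule1_left_scan_at_sentence
            else frozenset()
        )
        for cand in reversed([e for e in doc.sorted_entities() if e.end <= state.start]):
            if has_delim_between(doc.text, cand.end, state.start, delims):
                break
            if cand.label in POSITION_TYPES:
                target = cand
                break
    if target is None:
        return None
    return Relation(_PROTO_ID, state.id, target.id, _POSITION_RELATION[target.label])


def rule2_scope_attachment(
    doc: AnnotatedDocument, scope: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> Optional[Relation]:
    """Attach a scope qualifier to the position it delimits.

    Scanning rightward — skipping entities that are neither ``Pos_Pri``
    nor ``Pos_Sub`` (stacked scopes each reach past one another to the
    same head) and stopping at the clause boundary when configured —
    the first ``Pos_Pri``/``Pos_Sub`` becomes the subject of an
    ``SSCP`` relation with the scope as object.
    """
    _require_label(scope, EntityType.POS_SCP)
    delims = (
        cfg.segmentation.clause_delims if cfg.rule2_stop_at_clause else frozenset()
    )
    for cand in doc.sorted_entities():
        if cand.start < scope.end:
            continue
        if has_delim_between(doc.text, scope.end, cand.start, delims):
            break
        if cand.label in (EntityType.POS_PRI, EntityType.POS_SUB):
            return Relation(_PROTO_ID, cand.id, scope.id, RelationType.SSCP)
    return None


def rule3_negation_scope(
    doc: AnnotatedDocument, neg: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> list[Relation]:
    """Negate every ``State``/``Symp_S`` between ``neg`` and the next
    "，" or "。"."""
    _require_label(neg, EntityType.NEG)
    delims = cfg.segmentation.clause_delims
    out = []
    for cand in doc.sorted_entities():
        if cand.start < neg.end:
            continue
        if has_delim_between(doc.text, neg.end, cand.start, delims):
            break
        if cand.label in SYMPTOM_TYPES:
            out.append(Relation(_PROTO_ID, cand.id, neg.id, RelationType.SN))
    return out


def rule4_time_scope(
    doc: AnnotatedDocument, time: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> list[Relation]:
    """Stamp every ``State``/``Symp_S`` between this ``Time`` and the
    next ``Time`` entity (to document end when none follows); the range
    crosses clause and sentence delimiters."""
    _require_label(time, EntityType.TIME)
    later_times = [
        t for t in doc.entities if t.label is EntityType.TIME and t.start > time.start
    ]
    hi = min((t.start for t in later_times), default=len(doc.text))
    return [
        Relation(_PROTO_ID, cand.id, time.id, RelationType.STI)
        for cand in doc.sorted_entities()
        if cand.label in SYMPTOM_TYPES and time.end <= cand.start < hi
    ]


def rule5_clause_attributes(
    doc: AnnotatedDocument, attr: Entity, cfg: RuleConfig = DEFAULT_RULES
) -> list[Relation]:
    """Attach a condition/trend/frequency/severity entity to all
    ``State``/``Symp_S`` entities in the same clause."""
    _require_label(attr, *ATTRIBUTE_TYPES)
    clause = next(
        (
            (lo, hi)
            for lo, hi in clause_spans(doc.text, cfg.segmentation)
            if lo <= attr.start < hi
        ),
        None,
    )
    if clause is None:
        return []
    lo, hi = clause
    rtype = ATTRIBUTE_RELATION[attr.label]
    return [
        Relation(_PROTO_ID, cand.id, attr.id, rtype)
        for cand in doc.sorted_entities()
        if cand.label in SYMPTOM_TYPES and lo <= cand.start < hi and cand.id != attr.id
    ]


def _chain_subordinates(doc: AnnotatedDocument, relations: list[Relation],
                        cfg: RuleConfig) -> list[Relation]:
    """Optional progressive-annotation chaining: a ``Pos_Sub`` that is an
    ``SSub`` object links to the nearest ``Pos_Pri`` leftward in its
    sentence, else the nearest rightward."""
    out = []
    sub_ids = {r.object_id for r in relations if r.type is RelationType.SSUB}
    delims = cfg.segmentation.sentence_delims
    pris = doc.entities_of(EntityType.POS_PRI)
    for sub_id in sorted(sub_ids):
        sub = doc.entity_by_id(sub_id)
        if sub is None:
            continue
        lefts = [p for p in pris if p.end <= sub.start
                 and not has_delim_between(doc.text, p.end, sub.start, delims)]
        rights = [p for p in pris if p.start >= sub.end
                  and not has_delim_between(doc.text, sub.end, p.start, delims)]
        target = lefts[-1] if lefts else (rights[0] if rights else None)
        if target is not None:
            out.append(Relation(_PROTO_ID, sub.id, target.id, RelationType.SPRI))
    return out


def extract_relations(
    doc: AnnotatedDocument, cfg: RuleConfig = DEFAULT_RULES
) -> AnnotatedDocument:
    """Run all five rules over a document's entities.

    Returns a new document whose relations are the deduplicated union
    of the rule outputs; any pre-existing relations are replaced, never
    merged (gold preservation is the caller's job).  Output is
    independent of entity input order.
    """
    proto: list[Relation] = []
    for e in doc.sorted_entities():
        if e.label is EntityType.STATE:
            r = rule1_position_for_state(doc, e, cfg)
            if r is not None:
                proto.append(r)
        elif e.label is EntityType.POS_SCP:
            r = rule2_scope_attachment(doc, e, cfg)
            if r is not None:
                proto.append(r)
        elif e.label is EntityType.NEG:
            proto.extend(rule3_negation_scope(doc, e, cfg))
        elif e.label is EntityType.TIME:
            proto.extend(rule4_time_scope(doc, e, cfg))
        elif e.label in ATTRIBUTE_TYPES:
            proto.extend(rule5_clause_attributes(doc, e, cfg))
    if cfg.chain_subordinate_to_primary:
        proto.extend(_chain_subordinates(doc, proto, cfg))

    seen: set[tuple] = set()
    next_id = max((e.id for e in doc.entities), default=-1) + 1
    relations: list[Relation] = []
    for r in proto:
        if r.key() in seen:
            continue
        seen.add(r.key())
        relations.append(replace(r, id=next_id))
        next_id += 1
    return AnnotatedDocument(
        doc_id=doc.doc_id, text=doc.text, entities=list(doc.entities), relations=relations
    )
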