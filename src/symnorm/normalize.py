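"""Combine entities and relations into standardized symptom rows.

Each ``State``/``Symp_S`` entity is a root.  Three combination steps
build one table line per root x position path:

* position paths — starting from the root, recursively follow the
  position relations (``SPri``/``SSub``/``SSCP``); each branch point
  yields a separate output line; a visited set breaks cycles;
* attribute collection — the object texts of the root's ``STi``/``SN``/
  ``SC``/``SF``/``SQual``/``SQuant``/``STr`` relations, same-type values
  joined with ";" in document order;
* assembly — path elements fill the scope/primary/subordinate columns,
  attributes the remaining columns; "-" marks an absent value.

A compound pulse description such as 脉弦细弱 (one position, three
states) therefore unfolds into three rows, one per single symptom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .schema import (
    POSITION_TYPES,
    SYMPTOM_TYPES,
    AnnotatedDocument,
    Entity,
    EntityType,
    RelationType,
)

#: relation types followed when building position paths
_POSITION_RELS = {RelationType.SPRI, RelationType.SSUB, RelationType.SSCP}

#: attribute relation type -> normalized column name
_ATTR_COLUMN = {
    RelationType.STI: "time",
    RelationType.SN: "negation",
    RelationType.SC: "condition",
    RelationType.SF: "frequency",
    RelationType.SQUAL: "severity_qualitative",
    RelationType.SQUANT: "severity_quantitative",
    RelationType.STR: "trend",
}

_POSITION_COLUMN = {
    EntityType.POS_SCP: "position_scope",
    EntityType.POS_PRI: "position_primary",
    EntityType.POS_SUB: "position_subordinate",
}

MISSING = "-"


@dataclass(frozen=True)
class NormalizedRow:
    """One standardized symptom statement; "-" marks an absent value."""

    doc_id: str
    time: str = MISSING
    position_scope: str = MISSING
    position_primary: str = MISSING
    position_subordinate: str = MISSING
    state_or_symptom: str = MISSING
    negation: str = MISSING
    condition: str = MISSING
    frequency: str = MISSING
    severity_qualitative: str = MISSING
    severity_quantitative: str = MISSING
    trend: str = MISSING

    def as_cells(self) -> tuple[str, ...]:
        return (
            self.doc_id,
            self.time,
            self.position_scope,
            self.position_primary,
            self.position_subordinate,
            self.state_or_symptom,
            self.negation,
            self.condition,
            self.frequency,
            self.severity_qualitative,
            self.severity_quantitative,
            self.trend,
        )


PositionPath = tuple[tuple[EntityType, str], ...]


def _require_root(root: Entity) -> None:
    if root.label not in SYMPTOM_TYPES:
        raise ValueError(
            f"entity {root.id} has label {root.label.value}; a normalization root "
            "must be State or Symp_S"
        )


def _outgoing(doc: AnnotatedDocument) -> dict[int, list[tuple[Entity, EntityType]]]:
    """subject id -> position objects, ordered by object span."""
    out: dict[int, list[tuple[Entity, EntityType]]] = {}
    pairs = []
    for r in doc.relations:
        if r.type not in _POSITION_RELS:
            continue
        obj = doc.entity_by_id(r.object_id)
        if obj is None or obj.label not in POSITION_TYPES:
            continue
        pairs.append((r.subject_id, obj))
    for subject_id, obj in sorted(pairs, key=lambda p: (p[0], p[1].start, p[1].end)):
        out.setdefault(subject_id, []).append((obj, obj.label))
    return out


def position_paths(doc: AnnotatedDocument, root: Entity) -> list[PositionPath]:
    """All maximal position paths reachable from a symptom root.

    Depth-first recursion over the position relations; each branch point
    multiplies paths (different paths correspond to different output
    lines); cycles are broken by a visited set.  A root with no position
    relation yields a single empty path.
    """
    _require_root(root)
    outgoing = _outgoing(doc)
    paths: list[PositionPath] = []

    def walk(node_id: int, trail: list[tuple[EntityType, str]], visited: set[int]) -> None:
        nexts = [
            (obj, label)
            for obj, label in outgoing.get(node_id, [])
            if obj.id not in visited
        ]
        if not nexts:
            paths.append(tuple(trail))
            return
        for obj, label in nexts:
            walk(obj.id, trail + [(label, obj.text)], visited | {obj.id})

    walk(root.id, [], {root.id})
    return paths


def attribute_map(doc: AnnotatedDocument, root: Entity) -> dict[str, str]:
    """Collect attribute texts for a root, keyed by normalized column.

    Multiple values of the same relation type are joined with ";" in
    document order of the object entities.
    """
    _require_root(root)
    collected: dict[str, list[tuple[int, str]]] = {}
    for r in doc.relations:
        if r.subject_id != root.id or r.type not in _ATTR_COLUMN:
            continue
        obj = doc.entity_by_id(r.object_id)
        if obj is None:
            continue
        collected.setdefault(_ATTR_COLUMN[r.type], []).append((obj.start, obj.text))
    return {
        col: ";".join(text for _, text in sorted(vals))
        for col, vals in collected.items()
    }


def normalize_document(doc: AnnotatedDocument) -> list[NormalizedRow]:
    """One row per (symptom root x position path), in document order.

    Path elements fill the scope/primary/subordinate columns (multiple
    same-column elements within one path joined with ";"); the attribute
    map fills the remaining columns.  A document with zero relations
    yields exactly one bare row per root — no information is invented.
    Identical rows arising from redundant gold relations are kept.
    """
    rows: list[NormalizedRow] = []
    for root in doc.entities_of(*SYMPTOM_TYPES):
        attrs = attribute_map(doc, root)
        for path in position_paths(doc, root):
            cols: dict[str, list[str]] = {}
            for etype, text in path:
                cols.setdefault(_POSITION_COLUMN[etype], []).append(text)
            rows.append(
                NormalizedRow(
                    doc_id=doc.doc_id,
                    state_or_symptom=root.text,
                    **{c: ";".join(v) for c, v in cols.items()},
                    **attrs,
                )
            )
    return rows


def normalize_corpus(docs: Sequence[AnnotatedDocument]) -> list[NormalizedRow]:
    return [row for doc in docs for row in normalize_document(doc)]
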