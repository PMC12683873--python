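"""Core annotation schema for fine-grained TCM symptom information.

The schema follows the "position + state" view of Chinese symptom
descriptions: a symptom is either a self-contained element (``Symp_S``)
or a ``State`` that must combine with a position.  Positions split into
a scope qualifier (``Pos_SCP``, e.g. 左 "left" / 双 "both"), a primary
subject (``Pos_Pri``, e.g. 下肢 "lower limbs") and a subordinate aspect
(``Pos_Sub``, e.g. quantity/colour/quality).  Seven modifier entity
types carry onset time, negation, triggering condition, frequency,
qualitative and quantitative severity, and trend.

Ten directed relation types connect a subject entity to an object
entity; which entity types may appear at either end is fixed by
:data:`RELATION_CONSTRAINTS`.  Documents are validated against the
annotation principles (no overlapping spans, no nesting, offsets that
match the text, relations that respect the constraint matrix);
violations are reported as data, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class EntityType(str, Enum):
    """The 12 entity labels of the fine-grained symptom schema."""

    STATE = "State"
    POS_PRI = "Pos_Pri"
    POS_SCP = "Pos_SCP"
    POS_SUB = "Pos_Sub"
    SYMP_S = "Symp_S"
    TIME = "Time"
    COND = "Cond"
    NEG = "Neg"
    FREQ = "Freq"
    SEV_QUAL = "Sev_Qual"
    SEV_QUANT = "Sev_Quant"
    TREND = "Trend"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, Enum):
    """The 10 directed relation labels, named ``subject_object``."""

    SPRI = "SPri"
    SSUB = "SSub"
    SSCP = "SSCP"
    SN = "SN"
    STI = "STi"
    SC = "SC"
    SF = "SF"
    SQUAL = "SQual"
    SQUANT = "SQuant"
    STR = "STr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Position entity types, in "progressive annotation" order
#: (subordinate -> primary -> scope).
POSITION_TYPES = frozenset(
    {EntityType.POS_SCP, EntityType.POS_PRI, EntityType.POS_SUB}
)

#: Symptom-bearing entity types: the subjects of every attribute relation.
SYMPTOM_TYPES = frozenset({EntityType.STATE, EntityType.SYMP_S})

#: Attribute entity types handled by the clause-scoped rule (rule 5).
ATTRIBUTE_TYPES = frozenset(
    {
        EntityType.COND,
        EntityType.TREND,
        EntityType.FREQ,
        EntityType.SEV_QUAL,
        EntityType.SEV_QUANT,
    }
)

#: Constraint matrix: relation type -> (allowed subject labels, object label).
RELATION_CONSTRAINTS: dict[RelationType, tuple[frozenset[EntityType], EntityType]] = {
    RelationType.SPRI: (
        frozenset({EntityType.STATE, EntityType.POS_SUB}),
        EntityType.POS_PRI,
    ),
    RelationType.SSUB: (frozenset({EntityType.STATE}), EntityType.POS_SUB),
    RelationType.SSCP: (
        frozenset({EntityType.STATE, EntityType.POS_PRI, EntityType.POS_SUB}),
        EntityType.POS_SCP,
    ),
    RelationType.SN: (SYMPTOM_TYPES, EntityType.NEG),
    RelationType.STI: (SYMPTOM_TYPES, EntityType.TIME),
    RelationType.SC: (SYMPTOM_TYPES, EntityType.COND),
    RelationType.SF: (SYMPTOM_TYPES, EntityType.FREQ),
    RelationType.SQUAL: (SYMPTOM_TYPES, EntityType.SEV_QUAL),
    RelationType.SQUANT: (SYMPTOM_TYPES, EntityType.SEV_QUANT),
    RelationType.STR: (SYMPTOM_TYPES, EntityType.TREND),
}

#: Attribute entity label -> relation type emitted by the clause rule.
ATTRIBUTE_RELATION: dict[EntityType, RelationType] = {
    EntityType.COND: RelationType.SC,
    EntityType.TREND: RelationType.STR,
    EntityType.FREQ: RelationType.SF,
    EntityType.SEV_QUAL: RelationType.SQUAL,
    EntityType.SEV_QUANT: RelationType.SQUANT,
}


@dataclass(frozen=True)
class Entity:
    """A typed character span.

    Offsets are 0-based, half-open counts of Unicode code points (not
    bytes), matching the annotation tool's export convention and keeping
    Chinese characters atomic.
    """

    id: int
    label: EntityType
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def key(self) -> tuple[int, int, str]:
        """Strict-evaluation key: boundaries plus type."""
        return (self.start, self.end, self.label.value)


@dataclass(frozen=True)
class Relation:
    """A typed directed pair: subject entity -> object entity."""

    id: int
    subject_id: int
    object_id: int
    type: RelationType

    def key(self) -> tuple[int, int, str]:
        return (self.subject_id, self.object_id, self.type.value)


@dataclass
class SegmentationConfig:
    """Clause/sentence delimiter sets.

    Clauses are bounded by the full-width comma "，" and period "。";
    sentences by "。" only.  The enumeration mark "、" is deliberately
    not a delimiter: negation and attribute scopes run across it.
    """

    clause_delims: frozenset[str] = frozenset({"，", "。"})
    sentence_delims: frozenset[str] = frozenset({"。"})

    def __post_init__(self) -> None:
        self.clause_delims = frozenset(self.clause_delims)
        self.sentence_delims = frozenset(self.sentence_delims)
        if not self.sentence_delims <= self.clause_delims:
            raise ValueError("sentence_delims must be a subset of clause_delims")


DEFAULT_SEGMENTATION = SegmentationConfig()


@dataclass
class AnnotatedDocument:
    """Text plus entity set plus relation set; the unit of all I/O and rules."""

    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    #: free-form metadata (e.g. adversarial perturbation log); not persisted
    meta: dict = field(default_factory=dict)

    def entity_by_id(self, entity_id: int) -> Optional[Entity]:
        for e in self.entities:
            if e.id == entity_id:
                return e
        return None

    def sorted_entities(self) -> list[Entity]:
        return sorted(self.entities, key=lambda e: (e.start, e.end))

    def entities_of(self, *labels: EntityType) -> list[Entity]:
        wanted = set(labels)
        return [e for e in self.sorted_entities() if e.label in wanted]

    def relation_keys(self) -> set[tuple]:
        """Strict relation keys resolved to entity span keys."""
        keys = set()
        for r in self.relations:
            s = self.entity_by_id(r.subject_id)
            o = self.entity_by_id(r.object_id)
            if s is None or o is None:
                continue
            keys.add((s.key(), o.key(), r.type.value))
        return keys


@dataclass(frozen=True)
class Violation:
    """One validity breach; ``where`` identifies the offending ids/spans."""

    kind: str  # span | text_mismatch | overlap | nesting | duplicate_entity |
    #            dangling | self_relation | constraint | duplicate_relation |
    #            suspicious_span (warning)
    message: str
    where: tuple = ()
    severity: str = "error"  # error | warning


def validate_document(
    doc: AnnotatedDocument,
    cfg: SegmentationConfig = DEFAULT_SEGMENTATION,
    include_warnings: bool = False,
) -> list[Violation]:
    """Check a document against the annotation principles.

    Returns every violation found (bad span, text mismatch, overlap,
    nesting, duplicate, dangling relation, constraint-matrix breach,
    self-relation); the empty list iff the document is valid.  With
    ``include_warnings`` suspicious spans (entities containing a clause
    delimiter) are reported too, as warnings.

    The check is idempotent and insensitive to entity/relation order.
    """
    out: list[Violation] = []
    n = len(doc.text)
    ok_entities: list[Entity] = []
    for e in sorted(doc.entities, key=lambda e: (e.start, e.end, e.label.value)):
        if not (0 <= e.start < e.end <= n):
            out.append(
                Violation("span", f"entity {e.id} span ({e.start},{e.end}) outside text of length {n}", (e.id,))
            )
            continue
        if doc.text[e.start : e.end] != e.text:
            out.append(
                Violation(
                    "text_mismatch",
                    f"entity {e.id} text {e.text!r} != document substring {doc.text[e.start:e.end]!r}",
                    (e.id,),
                )
            )
        ok_entities.append(e)

    seen_triples: set[tuple] = set()
    for e in ok_entities:
        triple = e.key()
        if triple in seen_triples:
            out.append(Violation("duplicate_entity", f"duplicate entity triple {triple}", (e.id,)))
        seen_triples.add(triple)
        if include_warnings and any(c in cfg.clause_delims for c in e.text):
            out.append(
                Violation(
                    "suspicious_span",
                    f"entity {e.id} text {e.text!r} contains a clause delimiter",
                    (e.id,),
                    severity="warning",
                )
            )

    spans = sorted({(e.start, e.end, e.id) for e in ok_entities})
    for a, (s1, e1, i1) in enumerate(spans):
        for s2, e2, i2 in spans[a + 1 :]:
            if s2 >= e1:  # touching spans (s2 == e1) are fine
                break
            kind = "nesting" if e2 <= e1 or s1 == s2 else "overlap"
            out.append(
                Violation(kind, f"entities {i1} ({s1},{e1}) and {i2} ({s2},{e2}) {kind}", (i1, i2))
            )

    by_id = {e.id: e for e in doc.entities}
    seen_rel: set[tuple] = set()
    for r in sorted(doc.relations, key=lambda r: (r.subject_id, r.object_id, r.type.value)):
        subj = by_id.get(r.subject_id)
        obj = by_id.get(r.object_id)
        if subj is None or obj is None:
            out.append(
                Violation("dangling", f"relation {r.id} references missing entity", (r.id,))
            )
            continue
        if r.subject_id == r.object_id:
            out.append(Violation("self_relation", f"relation {r.id} is reflexive", (r.id,)))
            continue
        allowed_subjects, allowed_object = RELATION_CONSTRAINTS[r.type]
        if subj.label not in allowed_subjects or obj.label is not allowed_object:
            out.append(
                Violation(
                    "constraint",
                    f"relation {r.id} ({r.type.value}) endpoints "
                    f"{subj.label.value}->{obj.label.value} breach the constraint matrix",
                    (r.id,),
                )
            )
        rk = r.key()
        if rk in seen_rel:
            out.append(Violation("duplicate_relation", f"duplicate relation {rk}", (r.id,)))
        seen_rel.add(rk)

    return out


def _split_spans(text: str, delims: frozenset[str]) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in delims:
            if i > start:
                spans.append((start, i))
            start = i + 1
    if len(text) > start:
        spans.append((start, len(text)))
    return spans


def clause_spans(
    text: str, cfg: SegmentationConfig = DEFAULT_SEGMENTATION
) -> list[tuple[int, int]]:
    """Half-open clause spans: text split on "，" and "。".

    Delimiters are excluded from the spans; a trailing segment without a
    delimiter is still emitted; the spans partition the non-delimiter
    characters.
    """
    return _split_spans(text, cfg.clause_delims)


def sentence_spans(
    text: str, cfg: SegmentationConfig = DEFAULT_SEGMENTATION
) -> list[tuple[int, int]]:
    """Half-open sentence spans: split on "。" only (commas do not split)."""
    return _split_spans(text, cfg.sentence_delims)


def has_delim_between(
    text: str, lo: int, hi: int, delims: Iterable[str]
) -> bool:
    """True iff any delimiter occurs in ``text[lo:hi]`` (lo/hi clipped)."""
    if hi <= lo:
        return False
    dset = set(delims)
    return any(c in dset for c in text[max(lo, 0) : min(hi, len(text))])
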