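"""Read/write annotation JSONL (doccano relation-export dialect) and
normalized-row TSV tables.

One JSON object per line::

    {"id": 0, "text": "...",
     "entities":  [{"id", "label", "start_offset", "end_offset"}, ...],
     "relations": [{"id", "from_id", "to_id", "type"}, ...]}

``from_id`` is the relation subject, ``to_id`` the object.  Entity text
is recovered from the document text by offset; offsets count Unicode
code points.  Duplicate relations are collapsed silently on load (a
warning is logged).  Round-trips are identity modulo key order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

from .schema import AnnotatedDocument, Entity, EntityType, Relation, RelationType

logger = logging.getLogger(__name__)

#: Fixed column order of the normalized symptom table.
NORMALIZED_COLUMNS = (
    "doc_id",
    "time",
    "position_scope",
    "position_primary",
    "position_subordinate",
    "state_or_symptom",
    "negation",
    "condition",
    "frequency",
    "severity_qualitative",
    "severity_quantitative",
    "trend",
)

PathLike = Union[str, Path]


def _document_from_record(record: dict, fallback_id: str) -> AnnotatedDocument:
    text = record["text"]
    entities = []
    for ent in record.get("entities", []):
        start, end = int(ent["start_offset"]), int(ent["end_offset"])
        entities.append(
            Entity(
                id=int(ent["id"]),
                label=EntityType(ent["label"]),
                start=start,
                end=end,
                # out-of-range spans yield a clipped slice; the mismatch is
                # reported by validate_document, the document still loads
                text=text[start:end] if 0 <= start <= end <= len(text) else "",
            )
        )
    relations: list[Relation] = []
    seen: set[tuple] = set()
    for rel in record.get("relations", []):
        r = Relation(
            id=int(rel["id"]),
            subject_id=int(rel["from_id"]),
            object_id=int(rel["to_id"]),
            type=RelationType(rel["type"]),
        )
        if r.key() in seen:
            logger.warning("dropping duplicate relation %s in doc %s", r.key(), fallback_id)
            continue
        seen.add(r.key())
        relations.append(r)
    doc_id = str(record.get("id", fallback_id))
    return AnnotatedDocument(doc_id=doc_id, text=text, entities=entities, relations=relations)


def read_annotations(path: PathLike) -> list[AnnotatedDocument]:
    """Load a JSONL corpus; one :class:`AnnotatedDocument` per line.

    Raises ``ValueError`` naming the line number on a malformed line.
    Validity is *not* enforced here: a document with bad spans or
    dangling relations loads, and ``validate_document`` reports the
    violations.
    """
    docs: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                doc = _document_from_record(record, fallback_id=str(lineno - 1))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed record on line {lineno}: {exc}") from exc
            docs.append(doc)
    return docs


def document_to_record(doc: AnnotatedDocument) -> dict:
    return {
        "id": int(doc.doc_id) if doc.doc_id.isdigit() else doc.doc_id,
        "text": doc.text,
        "entities": [
            {
                "id": e.id,
                "label": e.label.value,
                "start_offset": e.start,
                "end_offset": e.end,
            }
            for e in doc.entities
        ],
        "relations": [
            {
                "id": r.id,
                "from_id": r.subject_id,
                "to_id": r.object_id,
                "type": r.type.value,
            }
            for r in doc.relations
        ],
    }


def write_annotations(docs: Iterable[AnnotatedDocument], path: PathLike) -> None:
    """Write documents as JSONL, one record per line, in input order."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_record(doc), ensure_ascii=False))
            fh.write("\n")


def write_normalized_rows(rows: Sequence, path: PathLike, missing_token: str = "-") -> None:
    """Write normalized symptom rows as a TSV table with a fixed header.

    Cells holding the internal absent marker "-" are emitted as
    ``missing_token``.  TSV is used because cell values may contain the
    full-width comma "，".
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NORMALIZED_COLUMNS) + "\n")
        for row in rows:
            cells = [
                missing_token if cell == "-" else cell for cell in row.as_cells()
            ]
            fh.write("\t".join(cells) + "\n")
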