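"""Synthetic present-illness narratives with construction-derived gold
relations.

Documents are assembled from the "position + state" grammar: sentences
(ended by "。") of clauses (joined by "，"), each clause either

    [Cond?][Neg?][Pos_SCP*][Pos_Pri][Pos_Sub?][State][attr*]

or, for self-contained symptoms,

    [Cond?][Neg?][Symp_S][attr*]

with an optional ``Time`` prefix at the sentence start.  Gold relations
are derived from the generation trace — which position a state was
built on, which negation governs it, which time span it falls under —
never by running the rule extractor, so the clean-mode equivalence test
(extractor output == gold) is a genuine oracle check.

One structural constraint keeps clean-mode gold and rule semantics
aligned: a clause that emits a ``Pos_Sub`` terminates its sentence.
Without it, a clause-final state flanked by its subordinate on the left
and the next clause's primary on the right would legitimately trigger
the neighbouring-primary rule while the construction intends the
subordinate attachment.

``inject_adversarial`` produces labelled perturbations that break the
rules' positional assumptions (an attribute drifting into the next
clause, a state written before its position, a negation after its
symptom) while keeping the gold relations pointing at the intended
semantics, so rule degradation is measurable.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, field

from .schema import (
    ATTRIBUTE_RELATION,
    AnnotatedDocument,
    Entity,
    EntityType,
    Relation,
    RelationType,
)

logger = logging.getLogger(__name__)


def default_lexicon() -> dict[EntityType, tuple[str, ...]]:
    """Chinese surface forms; no string contains a delimiter and no
    entry is a prefix of another, so greedy longest-match tagging
    recovers generated tokens exactly."""
    return {
        EntityType.STATE: ("疼痛", "肿胀", "麻木", "模糊", "弦", "细", "弱", "稠"),
        EntityType.POS_PRI: ("下肢", "手小指", "脉", "口", "头", "腰", "眼", "胃"),
        EntityType.POS_SCP: ("双", "左", "右"),
        EntityType.POS_SUB: ("皮肤", "颜色", "质地"),
        EntityType.SYMP_S: ("咳嗽", "发热", "恶心", "乏力", "失眠"),
        EntityType.TIME: ("6年前", "3天前", "半月前", "昨日"),
        EntityType.NEG: ("无", "未见", "不"),
        EntityType.COND: ("在下蹲或按压时", "活动时", "受凉后"),
        EntityType.FREQ: ("时有", "偶有", "反复"),
        EntityType.SEV_QUAL: ("明显", "剧烈", "轻度"),
        EntityType.SEV_QUANT: ("3次", "10分"),
        EntityType.TREND: ("加重", "至今未缓解", "逐渐缓解"),
    }


def ascii_lexicon() -> dict[EntityType, tuple[str, ...]]:
    """ASCII placeholder surfaces for debugging; same structure."""
    return {
        EntityType.STATE: ("pain", "swell", "numb"),
        EntityType.POS_PRI: ("limb", "head", "pulse"),
        EntityType.POS_SCP: ("both", "leftof"),
        EntityType.POS_SUB: ("skin", "color"),
        EntityType.SYMP_S: ("cough", "fever"),
        EntityType.TIME: ("6yago", "3dago"),
        EntityType.NEG: ("no", "without"),
        EntityType.COND: ("onwalk", "oncold"),
        EntityType.FREQ: ("often", "rarely"),
        EntityType.SEV_QUAL: ("marked", "mild"),
        EntityType.SEV_QUANT: ("3x", "10pt"),
        EntityType.TREND: ("worsen", "easing"),
    }


@dataclass
class SynthConfig:
    """Generator settings.

    Default probabilities echo the composition reported for the
    GDTCM-500 annotation study: self-contained symptoms are roughly a
    fifth of symptom roots, scope qualifiers mark about a fifth of
    positional clauses and subordinates rather fewer, negation governs
    about a fifth of clauses, onset times head most sentences, and
    quantitative severity is the rarest modifier.
    """

    seed: int = 0
    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (2, 4)
    clauses_per_sentence: tuple[int, int] = (1, 3)
    p_time: float = 0.6  # per sentence
    p_neg: float = 0.20
    p_scope: float = 0.18
    p_second_scope: float = 0.05
    p_sub: float = 0.085
    p_cond: float = 0.06
    p_freq: float = 0.065
    p_sev_qual: float = 0.07
    p_sev_quant: float = 0.015
    p_trend: float = 0.05
    symp_s_probability: float = 0.18
    adversarial_rate: float = 0.0
    lexicon: dict[EntityType, tuple[str, ...]] = field(default_factory=default_lexicon)

    def __post_init__(self) -> None:
        for name in (
            "p_time", "p_neg", "p_scope", "p_second_scope", "p_sub", "p_cond",
            "p_freq", "p_sev_qual", "p_sev_quant", "p_trend",
            "symp_s_probability", "adversarial_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("sentences_per_doc", "clauses_per_sentence"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name}=({lo},{hi}) is not a nonempty range of counts >= 1")
        for etype in (EntityType.STATE, EntityType.POS_PRI):
            if not self.lexicon.get(etype):
                raise ValueError(f"lexicon must provide surfaces for {etype.value}")


class _Builder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.text: list[str] = []
        self.pos = 0
        self.entities: list[Entity] = []
        self.relations: list[Relation] = []
        self._next_rel_id = 10_000  # offset keeps entity/relation ids distinct

    def emit(self, label: EntityType, surface: str) -> Entity:
        e = Entity(len(self.entities), label, self.pos, self.pos + len(surface), surface)
        self.entities.append(e)
        self.text.append(surface)
        self.pos += len(surface)
        return e

    def literal(self, s: str) -> None:
        self.text.append(s)
        self.pos += len(s)

    def relate(self, subject: Entity, obj: Entity, rtype: RelationType) -> None:
        self.relations.append(Relation(self._next_rel_id, subject.id, obj.id, rtype))
        self._next_rel_id += 1

    def build(self) -> AnnotatedDocument:
        return AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self.text),
            entities=self.entities,
            relations=self.relations,
        )


def generate_document(cfg: SynthConfig, doc_index: int) -> AnnotatedDocument:
    """One synthetic narrative with trace-derived gold relations.

    Deterministic: the same (config, index) pair always yields the same
    document.  The result always passes ``validate_document``.
    """
    rng = random.Random(cfg.seed * 1_000_003 + doc_index)
    b = _Builder(doc_id=str(doc_index))
    lex = cfg.lexicon

    def pick(etype: EntityType) -> str:
        return rng.choice(lex[etype])

    current_time: Entity | None = None
    n_sentences = rng.randint(*cfg.sentences_per_doc)
    for _ in range(n_sentences):
        if cfg.p_time and lex.get(EntityType.TIME) and rng.random() < cfg.p_time:
            current_time = b.emit(EntityType.TIME, pick(EntityType.TIME))
        n_clauses = rng.randint(*cfg.clauses_per_sentence)
        for ci in range(n_clauses):
            if ci > 0:
                b.literal("，")
            cond = None
            if lex.get(EntityType.COND) and rng.random() < cfg.p_cond:
                cond = b.emit(EntityType.COND, pick(EntityType.COND))
            neg = None
            if lex.get(EntityType.NEG) and rng.random() < cfg.p_neg:
                neg = b.emit(EntityType.NEG, pick(EntityType.NEG))

            sub = None
            if lex.get(EntityType.SYMP_S) and rng.random() < cfg.symp_s_probability:
                root = b.emit(EntityType.SYMP_S, pick(EntityType.SYMP_S))
            else:
                scopes = []
                if lex.get(EntityType.POS_SCP):
                    if rng.random() < cfg.p_scope:
                        scopes.append(b.emit(EntityType.POS_SCP, pick(EntityType.POS_SCP)))
                        if rng.random() < cfg.p_second_scope:
                            scopes.append(b.emit(EntityType.POS_SCP, pick(EntityType.POS_SCP)))
                pri = b.emit(EntityType.POS_PRI, pick(EntityType.POS_PRI))
                if lex.get(EntityType.POS_SUB) and rng.random() < cfg.p_sub:
                    sub = b.emit(EntityType.POS_SUB, pick(EntityType.POS_SUB))
                root = b.emit(EntityType.STATE, pick(EntityType.STATE))
                # position chain: the state attaches to the innermost
                # position present; the scope's head is the primary
                if sub is not None:
                    b.relate(root, sub, RelationType.SSUB)
                else:
                    b.relate(root, pri, RelationType.SPRI)
                for scp in scopes:
                    b.relate(pri, scp, RelationType.SSCP)

            if cond is not None:
                b.relate(root, cond, RelationType.SC)
            if neg is not None:
                b.relate(root, neg, RelationType.SN)
            if current_time is not None:
                b.relate(root, current_time, RelationType.STI)
            for etype, prob in (
                (EntityType.FREQ, cfg.p_freq),
                (EntityType.SEV_QUAL, cfg.p_sev_qual),
                (EntityType.SEV_QUANT, cfg.p_sev_quant),
                (EntityType.TREND, cfg.p_trend),
            ):
                if lex.get(etype) and rng.random() < prob:
                    attr = b.emit(etype, pick(etype))
                    b.relate(root, attr, ATTRIBUTE_RELATION[etype])

            if sub is not None:
                break  # a subordinate-bearing clause closes its sentence
        b.literal("。")
    return b.build()


def generate_corpus(cfg: SynthConfig) -> list[AnnotatedDocument]:
    """``cfg.n_docs`` documents, reproducible from the seed; adversarial
    perturbations applied at ``cfg.adversarial_rate``."""
    rng = random.Random(cfg.seed ^ 0x5EED)
    docs = []
    for i in range(cfg.n_docs):
        doc = generate_document(cfg, i)
        if cfg.adversarial_rate > 0.0:
            doc = inject_adversarial(doc, cfg, rng)
        docs.append(doc)
    hist = entity_type_histogram(docs)
    logger.info("generated %d docs; entity-type histogram: %s", len(docs), dict(hist))
    return docs


def entity_type_histogram(docs: list[AnnotatedDocument]) -> Counter:
    return Counter(e.label.value for doc in docs for e in doc.entities)


# ---------------------------------------------------------------------------
# adversarial perturbations

_Token = object  # Entity | str


def _tokens(doc: AnnotatedDocument) -> list:
    """Decompose a document into entity tokens and literal gap strings."""
    toks: list = []
    pos = 0
    for e in doc.sorted_entities():
        if e.start > pos:
            toks.append(doc.text[pos : e.start])
        toks.append(e)
        pos = e.end
    if pos < len(doc.text):
        toks.append(doc.text[pos:])
    return toks


def _rebuild(doc: AnnotatedDocument, toks: list) -> AnnotatedDocument:
    b = _Builder(doc.doc_id)
    id_map: dict[int, Entity] = {}
    for tok in toks:
        if isinstance(tok, Entity):
            id_map[tok.id] = b.emit(tok.label, tok.text)
        else:
            b.literal(tok)
    entities = list(b.entities)
    # re-key relations onto the rebuilt entities, preserving labels/ids
    rebuilt = []
    for r in doc.relations:
        s = id_map.get(r.subject_id)
        o = id_map.get(r.object_id)
        if s is None or o is None:
            continue
        rebuilt.append(Relation(r.id, s.id, o.id, r.type))
    out = AnnotatedDocument(doc.doc_id, "".join(b.text), entities, rebuilt)
    out.meta = dict(doc.meta)
    return out


def _ent_indices(toks: list, pred) -> list[int]:
    return [i for i, t in enumerate(toks) if isinstance(t, Entity) and pred(t)]


def inject_adversarial(
    doc: AnnotatedDocument, cfg: SynthConfig, rng: random.Random
) -> AnnotatedDocument:
    """With probability ``cfg.adversarial_rate`` apply one labelled
    perturbation; gold relations keep their intended semantics, so rule
    errors become measurable.  Rate 0 returns the document unchanged.

    Perturbations:

    * ``attr_next_clause`` — an attribute entity drifts past the next
      clause delimiter (the clause-scope rule then mislinks or misses);
    * ``state_before_position`` — a [primary][state] pair is written
      state-first (the neighbouring-primary rule still resolves it);
    * ``neg_after_symptom`` — a negation moves behind its symptom (the
      rightward negation scan then misses it).
    """
    if cfg.adversarial_rate <= 0.0 or rng.random() >= cfg.adversarial_rate:
        return doc
    toks = _tokens(doc)
    attempts = ["attr_next_clause", "state_before_position", "neg_after_symptom"]
    rng.shuffle(attempts)
    for kind in attempts:
        if kind == "attr_next_clause":
            cands = _ent_indices(
                toks, lambda e: e.label in ATTRIBUTE_RELATION and e.label is not EntityType.COND
            )
            if not cands:
                continue
            i = rng.choice(cands)
            attr = toks.pop(i)
            # find the next delimiter gap and re-insert the attribute
            # just beyond it (creating a trailing clause at sentence end)
            j = next(
                (k for k, t in enumerate(toks[i:], start=i)
                 if isinstance(t, str) and ("，" in t or "。" in t)),
                None,
            )
            if j is None:
                toks.extend(["，", attr])
            elif "，" in toks[j]:
                toks.insert(j + 1, attr)
            else:  # sentence end: open a fresh clause before the "。"
                toks[j:j] = ["，", attr]
            perturbed = (kind, attr.id)
            break
        if kind == "state_before_position":
            cands = [
                i
                for i in _ent_indices(toks, lambda e: e.label is EntityType.POS_PRI)
                if i + 1 < len(toks)
                and isinstance(toks[i + 1], Entity)
                and toks[i + 1].label is EntityType.STATE
            ]
            if not cands:
                continue
            i = rng.choice(cands)
            toks[i], toks[i + 1] = toks[i + 1], toks[i]
            perturbed = (kind, toks[i].id)
            break
        if kind == "neg_after_symptom":
            cands = [
                i
                for i in _ent_indices(toks, lambda e: e.label is EntityType.NEG)
                if any(
                    isinstance(t, Entity)
                    and t.label in (EntityType.STATE, EntityType.SYMP_S)
                    for t in toks[i + 1 :][:6]
                )
            ]
            if not cands:
                continue
            i = rng.choice(cands)
            neg = toks.pop(i)
            j = next(
                k
                for k, t in enumerate(toks[i:], start=i)
                if isinstance(t, Entity)
                and t.label in (EntityType.STATE, EntityType.SYMP_S)
            )
            toks.insert(j + 1, neg)
            perturbed = (kind, neg.id)
            break
    else:
        return doc
    out = _rebuild(replace_meta(doc, perturbed), toks)
    return out


def replace_meta(doc: AnnotatedDocument, perturbed: tuple) -> AnnotatedDocument:
    log = list(doc.meta.get("perturbations", []))
    log.append({"kind": perturbed[0], "entity_id": perturbed[1]})
    doc = AnnotatedDocument(doc.doc_id, doc.text, doc.entities, doc.relations,
                            meta={**doc.meta, "perturbations": log})
    return doc
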