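"""Small worked-example documents built from classic clinical phrasings.

These are hand-annotated miniatures used throughout the documentation
and tests:

* ``lower_limb_pain()`` — 6年前双下肢疼痛，无肿胀。("six years ago,
  pain in both lower limbs, no swelling"): an onset time scoping two
  states, a scope qualifier on the primary position, a shared primary
  described once, and a negated second state;
* ``compound_pulse()`` — 脉弦细弱。("the pulse is stringy, thready and
  weak"): one position carrying three states — the compound symptom
  that normalization must unfold into three single-symptom rows;
* ``left_little_finger()`` — 左手小指疼痛。("pain in the little finger
  of the left hand"): maximize-coverage annotation of the progressive
  position 手小指, with the scope 左 attaching to it.

Gold relations are exactly what a careful annotator following the
guideline would produce (and what the extraction rules derive).
"""

from __future__ import annotations

from .schema import AnnotatedDocument, Entity, EntityType, Relation, RelationType

E = EntityType
R = RelationType


def lower_limb_pain() -> AnnotatedDocument:
    text = "6年前双下肢疼痛，无肿胀。"
    ents = [
        Entity(0, E.TIME, 0, 3, "6年前"),
        Entity(1, E.POS_SCP, 3, 4, "双"),
        Entity(2, E.POS_PRI, 4, 6, "下肢"),
        Entity(3, E.STATE, 6, 8, "疼痛"),
        Entity(4, E.NEG, 9, 10, "无"),
        Entity(5, E.STATE, 10, 12, "肿胀"),
    ]
    rels = [
        Relation(100, 3, 2, R.SPRI),   # 疼痛 -> 下肢
        Relation(101, 5, 2, R.SPRI),   # 肿胀 -> 下肢 (shared primary)
        Relation(102, 2, 1, R.SSCP),   # 下肢 -> 双
        Relation(103, 5, 4, R.SN),     # 肿胀 -> 无
        Relation(104, 3, 0, R.STI),    # 疼痛 -> 6年前
        Relation(105, 5, 0, R.STI),    # 肿胀 -> 6年前
    ]
    return AnnotatedDocument("D1", text, ents, rels)


def compound_pulse() -> AnnotatedDocument:
    text = "脉弦细弱。"
    ents = [
        Entity(0, E.POS_PRI, 0, 1, "脉"),
        Entity(1, E.STATE, 1, 2, "弦"),
        Entity(2, E.STATE, 2, 3, "细"),
        Entity(3, E.STATE, 3, 4, "弱"),
    ]
    rels = [
        Relation(100, 1, 0, R.SPRI),
        Relation(101, 2, 0, R.SPRI),
        Relation(102, 3, 0, R.SPRI),
    ]
    return AnnotatedDocument("D2", text, ents, rels)


def left_little_finger() -> AnnotatedDocument:
    text = "左手小指疼痛。"
    ents = [
        Entity(0, E.POS_SCP, 0, 1, "左"),
        Entity(1, E.POS_PRI, 1, 4, "手小指"),
        Entity(2, E.STATE, 4, 6, "疼痛"),
    ]
    rels = [
        Relation(100, 1, 0, R.SSCP),   # 手小指 -> 左
        Relation(101, 2, 1, R.SPRI),   # 疼痛 -> 手小指
    ]
    return AnnotatedDocument("D3", text, ents, rels)
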