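"""The five relation-extraction rules, individually and orchestrated."""

import random

import pytest

from symnorm.rules import (
    RuleConfig,
    extract_relations,
    neighbor_entities,
    rule1_position_for_state,
    rule2_scope_attachment,
    rule3_negation_scope,
    rule4_time_scope,
    rule5_clause_attributes,
)
from symnorm.schema import (
    AnnotatedDocument,
    Entity,
    EntityType,
    RelationType,
    validate_document,
)

E = EntityType
R = RelationType


def mkdoc(*tokens, doc_id="t"):
    """Assemble a document from (label-or-None, text) tokens; None = literal."""
    text, entities, pos = [], [], 0
    for label, surface in tokens:
        if label is not None:
            entities.append(Entity(len(entities), label, pos, pos + len(surface), surface))
        text.append(surface)
        pos += len(surface)
    return AnnotatedDocument(doc_id, "".join(text), entities)


def by_text(doc, text, label=None):
    return next(
        e for e in doc.entities if e.text == text and (label is None or e.label is label)
    )


def keys(doc, relations):
    out = set()
    for r in relations:
        s, o = doc.entity_by_id(r.subject_id), doc.entity_by_id(r.object_id)
        out.add((s.text, o.text, r.type.value))
    return out


class TestNeighbors:
    def test_d1_pain_neighbors(self, d1):
        left, right = neighbor_entities(d1, by_text(d1, "疼痛"))
        assert (left.text, right.text) == ("下肢", "无")

    def test_d2_middle_state(self, d2):
        left, right = neighbor_entities(d2, by_text(d2, "弦"))
        assert (left.text, right.text) == ("脉", "细")

    def test_single_entity_doc(self):
        doc = mkdoc((E.SYMP_S, "咳嗽"), (None, "。"))
        assert neighbor_entities(doc, doc.entities[0]) == (None, None)

    def test_sentence_bounding_hides_cross_period_neighbor(self):
        doc = mkdoc((E.POS_PRI, "脉"), (None, "。"), (E.STATE, "弱"), (None, "。"))
        left, right = neighbor_entities(doc, by_text(doc, "弱"))
        assert left is None and right is None
        cfg = RuleConfig(bound_rule1_left_scan_at_sentence=False)
        left, _ = neighbor_entities(doc, by_text(doc, "弱"), cfg)
        assert left.text == "脉"


class TestRule1:
    def test_case3_left_primary(self, d1):
        r = rule1_position_for_state(d1, by_text(d1, "疼痛"))
        assert keys(d1, [r]) == {("疼痛", "下肢", "SPri")}

    def test_case3_scan_through_states(self, d2):
        r = rule1_position_for_state(d2, by_text(d2, "弱"))
        assert keys(d2, [r]) == {("弱", "脉", "SPri")}

    def test_case1_both_primary_neighbors_pick_left(self):
        doc = mkdoc((E.POS_PRI, "口"), (E.STATE, "干"), (E.POS_PRI, "眼"), (None, "。"))
        r = rule1_position_for_state(doc, by_text(doc, "干"))
        assert keys(doc, [r]) == {("干", "口", "SPri")}

    def test_case2_right_primary_only(self):
        doc = mkdoc((E.STATE, "干"), (E.POS_PRI, "口"), (None, "。"))
        r = rule1_position_for_state(doc, by_text(doc, "干"))
        assert keys(doc, [r]) == {("干", "口", "SPri")}

    def test_case3_subordinate_and_scope_targets(self):
        doc = mkdoc((E.POS_SUB, "质"), (None, "，"), (E.STATE, "稠"), (None, "。"))
        r = rule1_position_for_state(doc, by_text(doc, "稠"))
        assert r.type is R.SSUB
        doc = mkdoc((E.POS_SCP, "双"), (None, "，"), (E.STATE, "肿"), (None, "。"))
        r = rule1_position_for_state(doc, by_text(doc, "肿"))
        assert r.type is R.SSCP

    def test_left_scan_crosses_comma_but_not_period(self):
        doc = mkdoc((E.POS_PRI, "脉"), (None, "，"), (E.STATE, "弱"), (None, "。"))
        assert rule1_position_for_state(doc, by_text(doc, "弱")) is not None
        doc = mkdoc((E.POS_PRI, "脉"), (None, "。"), (E.STATE, "弱"), (None, "。"))
        assert rule1_position_for_state(doc, by_text(doc, "弱")) is None

    def test_no_position_found(self):
        doc = mkdoc((E.STATE, "弱"), (None, "。"))
        assert rule1_position_for_state(doc, doc.entities[0]) is None

    def test_wrong_label_rejected(self, d1):
        with pytest.raises(ValueError):
            rule1_position_for_state(d1, by_text(d1, "无"))


class TestRule2:
    def test_d1_scope(self, d1):
        r = rule2_scope_attachment(d1, by_text(d1, "双"))
        assert keys(d1, [r]) == {("下肢", "双", "SSCP")}

    def test_d3_progressive_position(self, d3):
        r = rule2_scope_attachment(d3, by_text(d3, "左"))
        assert keys(d3, [r]) == {("手小指", "左", "SSCP")}

    def test_stacked_scopes_share_one_head(self):
        doc = mkdoc((E.POS_SCP, "左"), (E.POS_SCP, "右"), (E.POS_PRI, "下肢"), (None, "。"))
        r_left = rule2_scope_attachment(doc, by_text(doc, "左"))
        r_right = rule2_scope_attachment(doc, by_text(doc, "右"))
        assert keys(doc, [r_left, r_right]) == {
            ("下肢", "左", "SSCP"), ("下肢", "右", "SSCP"),
        }

    def test_stops_at_clause_boundary(self):
        doc = mkdoc((E.POS_SCP, "左"), (None, "，"), (E.POS_PRI, "下肢"), (None, "。"))
        assert rule2_scope_attachment(doc, by_text(doc, "左")) is None
        cfg = RuleConfig(rule2_stop_at_clause=False)
        assert rule2_scope_attachment(doc, by_text(doc, "左"), cfg) is not None


class TestRule3:
    def test_d1_negation(self, d1):
        rels = rule3_negation_scope(d1, by_text(d1, "无"))
        assert keys(d1, rels) == {("肿胀", "无", "SN")}

    def test_enumeration_mark_does_not_stop_scan(self):
        doc = mkdoc(
            (E.NEG, "无"), (E.SYMP_S, "咳嗽"), (None, "、"), (E.SYMP_S, "发热"),
            (None, "，"), (E.SYMP_S, "恶心"), (None, "。"),
        )
        rels = rule3_negation_scope(doc, by_text(doc, "无"))
        assert keys(doc, rels) == {("咳嗽", "无", "SN"), ("发热", "无", "SN")}

    def test_negation_immediately_before_comma(self):
        doc = mkdoc((E.NEG, "无"), (None, "，"), (E.SYMP_S, "咳嗽"), (None, "。"))
        assert rule3_negation_scope(doc, by_text(doc, "无")) == []


class TestRule4:
    def test_d1_time_covers_both_states(self, d1):
        rels = rule4_time_scope(d1, by_text(d1, "6年前"))
        assert keys(d1, rels) == {("疼痛", "6年前", "STi"), ("肿胀", "6年前", "STi")}

    def test_two_times_partition_the_document(self):
        doc = mkdoc(
            (E.TIME, "6年前"), (E.SYMP_S, "咳嗽"), (None, "。"),
            (E.TIME, "昨日"), (E.SYMP_S, "发热"), (None, "。"),
        )
        first = rule4_time_scope(doc, by_text(doc, "6年前"))
        second = rule4_time_scope(doc, by_text(doc, "昨日"))
        assert keys(doc, first) == {("咳嗽", "6年前", "STi")}
        assert keys(doc, second) == {("发热", "昨日", "STi")}

    def test_states_before_first_time_get_nothing(self):
        doc = mkdoc((E.SYMP_S, "咳嗽"), (None, "，"), (E.TIME, "昨日"), (E.SYMP_S, "发热"), (None, "。"))
        rels = rule4_time_scope(doc, by_text(doc, "昨日"))
        assert keys(doc, rels) == {("发热", "昨日", "STi")}


class TestRule5:
    def test_condition_in_clause(self):
        doc = mkdoc((E.COND, "活动时"), (E.STATE, "疼痛"), (None, "。"))
        rels = rule5_clause_attributes(doc, by_text(doc, "活动时"))
        assert keys(doc, rels) == {("疼痛", "活动时", "SC")}

    def test_trend_reaches_all_states_in_clause(self):
        doc = mkdoc((E.STATE, "痛"), (E.TREND, "加重"), (E.STATE, "胀"), (None, "。"))
        rels = rule5_clause_attributes(doc, by_text(doc, "加重"))
        assert keys(doc, rels) == {("痛", "加重", "STr"), ("胀", "加重", "STr")}

    def test_attribute_alone_in_clause(self):
        doc = mkdoc((E.STATE, "痛"), (None, "，"), (E.TREND, "加重"), (None, "。"))
        assert rule5_clause_attributes(doc, by_text(doc, "加重")) == []


class TestExtractRelations:
    def test_d1_exact_relation_set(self, d1):
        pred = extract_relations(d1)
        assert pred.relation_keys() == d1.relation_keys()
        assert len(pred.relations) == 6
        assert validate_document(pred) == []

    def test_d2_three_spri(self, d2):
        pred = extract_relations(d2)
        assert pred.relation_keys() == d2.relation_keys()
        assert all(r.type is R.SPRI for r in pred.relations)

    def test_no_symptom_entities_no_relations(self):
        doc = mkdoc((E.POS_PRI, "脉"), (None, "，"), (E.TIME, "昨日"), (None, "。"))
        assert extract_relations(doc).relations == []

    def test_replaces_existing_relations(self, d1):
        pred1 = extract_relations(d1)
        pred2 = extract_relations(pred1)
        assert pred2.relation_keys() == pred1.relation_keys()

    def test_order_insensitive(self, d1):
        rng = random.Random(1)
        expected = extract_relations(d1).relation_keys()
        for _ in range(5):
            shuffled = AnnotatedDocument(d1.doc_id, d1.text, list(d1.entities))
            rng.shuffle(shuffled.entities)
            assert extract_relations(shuffled).relation_keys() == expected

    def test_chaining_links_subordinate_to_primary(self):
        doc = mkdoc((E.POS_PRI, "痰"), (E.POS_SUB, "质"), (E.STATE, "稠"), (None, "。"))
        plain = extract_relations(doc)
        assert keys(doc, plain.relations) == {("稠", "质", "SSub")}
        chained = extract_relations(doc, RuleConfig(chain_subordinate_to_primary=True))
        assert keys(doc, chained.relations) == {("稠", "质", "SSub"), ("质", "痰", "SPri")}
        assert validate_document(chained) == []
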