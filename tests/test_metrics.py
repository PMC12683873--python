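"""Strict scoring, agreement symmetry, and the annotation-rate metric."""

import pytest
from hypothesis import given, settings, strategies as st

from symnorm.metrics import annotation_rate, iaa_report, prf, strict_entity_prf, strict_relation_prf
from symnorm.rules import extract_relations
from symnorm.schema import AnnotatedDocument, Entity, EntityType, Relation, RelationType

E = EntityType


def doc_with_entities(doc_id, text, spans):
    ents = [
        Entity(i, label, s, e, text[s:e]) for i, (s, e, label) in enumerate(spans)
    ]
    return AnnotatedDocument(doc_id, text, ents)


TEXT = "abcdefghij"
#: five non-overlapping candidate spans
SPANS = [(0, 2, E.STATE), (2, 4, E.POS_PRI), (4, 6, E.NEG), (6, 8, E.SYMP_S), (8, 10, E.TIME)]


class TestStrictEntityPRF:
    def test_identical_corpora(self):
        a = [doc_with_entities("0", TEXT, SPANS)]
        b = [doc_with_entities("0", TEXT, SPANS)]
        s = strict_entity_prf(a, b)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_partial_overlap_counts(self):
        # gold 4 keys, pred 5, overlap 3: R=3/4, P=3/5, F1=2/3
        gold = [doc_with_entities("0", TEXT, SPANS[:4])]
        pred = [doc_with_entities("0", TEXT, SPANS[1:5] + [(0, 1, E.STATE)])]
        s = strict_entity_prf(gold, pred)
        assert s.recall == pytest.approx(0.75)
        assert s.precision == pytest.approx(0.6)
        assert s.f1 == pytest.approx(2 / 3)

    def test_correct_span_wrong_label_is_wrong(self):
        gold = [doc_with_entities("0", TEXT, [(0, 2, E.STATE)])]
        pred = [doc_with_entities("0", TEXT, [(0, 2, E.SYMP_S)])]
        s = strict_entity_prf(gold, pred)
        assert s.f1 == 0.0
        assert s.per_type["State"].recall == 0.0
        assert s.per_type["Symp_S"].precision == 0.0

    def test_mismatched_corpora_rejected(self):
        a = [doc_with_entities("0", TEXT, SPANS)]
        with pytest.raises(ValueError):
            strict_entity_prf(a, [doc_with_entities("1", TEXT, SPANS)])
        with pytest.raises(ValueError):
            strict_entity_prf(a, [doc_with_entities("0", TEXT[::-1], SPANS)])


class TestStrictRelationPRF:
    def test_rule_extraction_on_fixture_is_perfect(self, d1):
        pred = extract_relations(d1)
        s = strict_relation_prf([d1], [pred])
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_reversed_relation_is_wrong(self, d2):
        flipped = AnnotatedDocument(
            d2.doc_id, d2.text, list(d2.entities),
            [Relation(r.id, r.object_id, r.subject_id, r.type) for r in d2.relations],
        )
        s = strict_relation_prf([d2], [flipped])
        assert s.f1 == 0.0

    def test_empty_prediction_conventions(self, d2):
        empty = AnnotatedDocument(d2.doc_id, d2.text, list(d2.entities), [])
        s = strict_relation_prf([d2], [empty])
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    def test_micro_invariant_to_document_partitioning(self, d1, d2):
        pred1, pred2 = extract_relations(d1), extract_relations(d2)
        pooled = strict_relation_prf([d1, d2], [pred1, pred2])
        a = strict_relation_prf([d1], [pred1])
        b = strict_relation_prf([d2], [pred2])
        assert pooled.n_correct == a.n_correct + b.n_correct
        assert pooled.n_gold == a.n_gold + b.n_gold


class TestAgreement:
    @given(
        a=st.sets(st.sampled_from(range(len(SPANS))), max_size=5),
        b=st.sets(st.sampled_from(range(len(SPANS))), max_size=5),
    )
    @settings(derandomize=True, max_examples=100)
    def test_f1_symmetry_and_brute_force_oracle(self, a, b):
        """F1 is unchanged when the annotator sets are exchanged, and P/R
        match direct set arithmetic on the key sets."""
        da = [doc_with_entities("0", TEXT, [SPANS[i] for i in sorted(a)])]
        db = [doc_with_entities("0", TEXT, [SPANS[i] for i in sorted(b)])]
        fwd = iaa_report(da, db, "entities")
        rev = iaa_report(db, da, "entities")
        assert fwd.f1 == pytest.approx(rev.f1)
        assert (fwd.precision, fwd.recall) == (rev.recall, rev.precision)
        # independent oracle: plain set intersection over index sets
        inter = len(a & b)
        exp_p, exp_r, exp_f = prf(inter, len(a), len(b))
        assert fwd.precision == pytest.approx(exp_p)
        assert fwd.recall == pytest.approx(exp_r)
        assert fwd.f1 == pytest.approx(exp_f)
        assert 0.0 <= fwd.precision <= 1.0 and 0.0 <= fwd.f1 <= 1.0

    def test_disjoint_annotations(self):
        da = [doc_with_entities("0", TEXT, SPANS[:2])]
        db = [doc_with_entities("0", TEXT, SPANS[2:])]
        assert iaa_report(da, db, "entities").f1 == 0.0

    def test_equal_set_sizes_make_p_equal_r(self):
        da = [doc_with_entities("0", TEXT, SPANS[:3])]
        db = [doc_with_entities("0", TEXT, SPANS[1:4])]
        s = iaa_report(da, db, "entities")
        assert s.precision == s.recall == s.f1

    def test_unknown_level_rejected(self, d1):
        with pytest.raises(ValueError):
            iaa_report([d1], [d1], "tokens")


class TestAnnotationRate:
    def test_fully_covered_sentence(self):
        doc = doc_with_entities("0", "ab", [(0, 2, E.SYMP_S)])
        mean, breakdown = annotation_rate([doc])
        assert mean == 1.0 and breakdown == [("0", 0, 1.0)]

    def test_d1_eleven_of_thirteen_characters(self, d1):
        # 11 of 13 code points lie inside entity spans ("，" and "。" do not)
        mean, _ = annotation_rate([d1])
        assert mean == pytest.approx(11 / 13)

    def test_no_entities(self):
        doc = AnnotatedDocument("0", "ab。cd。", [])
        mean, breakdown = annotation_rate([doc])
        assert mean == 0.0 and len(breakdown) == 2

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            annotation_rate([])
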