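"""Validate an annotated narrative and inspect its segmentation.

Builds the worked example 6年前双下肢疼痛，无肿胀。("six years ago, pain
in both lower limbs, no swelling"), checks it against the annotation
principles, and shows the clause/sentence spans that bound rule scopes.
"""

from symnorm import clause_spans, sentence_spans, validate_document
from symnorm.fixtures import lower_limb_pain
from symnorm.schema import AnnotatedDocument, Entity, EntityType

doc = lower_limb_pain()
print("text:", doc.text)
for e in doc.sorted_entities():
    print(f"  [{e.start},{e.end}) {e.label.value:<8} {e.text}")

print("violations:", validate_document(doc))
print("clauses:  ", clause_spans(doc.text))
print("sentences:", sentence_spans(doc.text))
# The document is valid (no violations), splits into two clauses bounded
# by the full-width comma, and forms a single sentence ending at 。.

broken = AnnotatedDocument(
    "bad", doc.text,
    list(doc.entities) + [Entity(99, EntityType.SYMP_S, 5, 7, "肢疼")],
)
for v in validate_document(broken):
    print("broken doc:", v.kind, "-", v.message)
# The extra span straddles two existing entities, breaching the
# no-overlap principle; violations are reported as data, not exceptions.
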