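"""Derive relations from entity spans with the five extraction rules.

Each rule anchors on one entity family: states attach to positions,
scopes to their position head, negations/times/attributes to the
symptoms in their textual scope.
"""

from symnorm import extract_relations
from symnorm.fixtures import compound_pulse, left_little_finger, lower_limb_pain

for doc in (lower_limb_pain(), compound_pulse(), left_little_finger()):
    pred = extract_relations(doc)
    print(f"{doc.doc_id}: {doc.text}")
    for r in pred.relations:
        s = pred.entity_by_id(r.subject_id)
        o = pred.entity_by_id(r.object_id)
        print(f"  {r.type.value:<5} {s.text} -> {o.text}")
    agrees = pred.relation_keys() == doc.relation_keys()
    print(f"  matches hand annotation: {agrees}")
# D1 yields six relations (two SPri onto the shared primary 下肢, the
# scope, one negation, two times); the compound pulse 脉弦细弱 yields
# three SPri, one per single pulse quality; in 左手小指疼痛 the scope 左
# attaches to the progressive position 手小指.
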