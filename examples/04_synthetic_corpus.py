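"""Generate a synthetic annotated corpus and verify rule-gold agreement.

The generator assembles present-illness narratives from the
"position + state" grammar and derives gold relations from the
construction trace, so the rule extractor can be scored against an
independent reference.  In clean mode the rules recover the gold
exactly; adversarial perturbations (an attribute drifting into the next
clause, a reordered state, a displaced negation) make them fallible.
"""

from symnorm import (
    SynthConfig,
    entity_type_histogram,
    extract_relations,
    generate_corpus,
    strict_relation_prf,
)

clean = generate_corpus(SynthConfig(seed=42, n_docs=500))
print("sample:", clean[0].text)
print("entity-type histogram:", dict(entity_type_histogram(clean)))

pred = [extract_relations(d) for d in clean]
s = strict_relation_prf(clean, pred)
print(f"clean mode: P={s.precision:.4f} R={s.recall:.4f} F1={s.f1:.4f} "
      f"over {s.n_gold} gold relations")
# Clean-mode F1 is exactly 1.0: the extractor reproduces every
# construction-derived relation and invents none.

adv = generate_corpus(SynthConfig(seed=42, n_docs=500, adversarial_rate=0.5))
sa = strict_relation_prf(adv, [extract_relations(d) for d in adv])
print(f"adversarial (rate 0.5): P={sa.precision:.4f} R={sa.recall:.4f} F1={sa.f1:.4f}")
# Recall drops below 1: perturbed clauses break the positional
# assumptions the rules rely on, as they do in real clinical text.
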