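# symnorm

Fine-grained extraction and normalization of symptom information from
Traditional Chinese Medicine (TCM) electronic medical records.

Present-illness narratives in TCM EMRs are semi-structured: a single
clause like 6年前双下肢疼痛 ("six years ago, pain in both lower limbs")
interleaves onset time, scope, body position and symptom state, and
compounds like 脉弦细弱 nest three pulse qualities in four characters.
Coarse-grained "symptom" spans either swallow this structure or lose it.
`symnorm` implements the alternative: a 12-entity / 10-relation
annotation schema built on the **position + state** view of symptom
descriptions, deterministic rules that derive the relations from entity
spans, and combination rules that emit one standardized row per single
symptom. It is a library for clinical-NLP researchers and corpus
builders, with a thin CLI for shell pipelines.

## The schema and the method

**Entities (12).** A symptom is either self-contained (`Symp_S`, e.g.
咳嗽 "cough") or a `State` (e.g. 疼痛 "pain") that must combine with a
position: scope `Pos_SCP` (左/双), primary `Pos_Pri` (下肢/脉),
subordinate `Pos_Sub` (quantity/colour/quality). Seven modifiers carry
context: `Time`, `Neg`, `Cond`, `Freq`, `Sev_Qual`, `Sev_Quant`,
`Trend`.

**Relations (10).** Directed subject→object pairs named
`subject_object`: `SPri`, `SSub`, `SSCP` for the position chain and
`SN`, `STi`, `SC`, `SF`, `SQual`, `SQuant`, `STr` for the modifiers,
each with a fixed constraint matrix over endpoint types.

**Rule-based relation extraction (5 rules).** Anchored on clause ("，")
and sentence ("。") segmentation: a state attaches to a flanking
primary position or else to the first position found scanning left; a
scope attaches to the first primary/subordinate to its right; a
negation governs symptoms rightward up to the next clause delimiter; a
time stamps every symptom until the next time expression; condition /
trend / frequency / severity attach to all symptoms in their clause.

**Normalization (3 combination rules).** From each symptom root,
recursively follow the position relations (each branch point is a
separate output line), collect attribute texts per relation type
(";"-joined when repeated), and emit fixed-column rows:

```
doc_id  time  position_scope  position_primary  position_subordinate
state_or_symptom  negation  condition  frequency
severity_qualitative  severity_quantitative  trend
```

**Evaluation.** Strict span/relation scoring with
R = |y¹∩y²|/|y¹|, P = |y¹∩y²|/|y²|, F₁ = 2PR/(P+R); the same formulas
serve as pairwise inter-annotator agreement (F₁ is symmetric in the two
annotators). The annotation-rate metric (TCM-SIU) is the mean
per-sentence fraction of characters covered by entity spans.

Because the source clinical records are withheld for privacy, the
package ships a synthetic-corpus generator that assembles narratives
from the position + state grammar and derives gold relations from the
construction trace — an independent oracle for the rule extractor — and
a greedy longest-match dictionary tagger so the pipeline runs
end-to-end from raw text.

## Worked example

```python
from symnorm import extract_relations, normalize_document
from symnorm.fixtures import lower_limb_pain

doc = lower_limb_pain()          # 6年前双下肢疼痛，无肿胀。
pred = extract_relations(doc)    # 6 relations: SPri×2, SSCP, SN, STi×2
for row in normalize_document(pred):
    print("\t".join(row.as_cells()))
```

prints

```
D1	6年前	双	下肢	-	疼痛	-	-	-	-	-	-
D1	6年前	双	下肢	-	肿胀	无	-	-	-	-	-
```

two standardized statements: "pain, both lower limbs, since six years
ago" and "swelling, both lower limbs, since six years ago — negated".
The shared primary 下肢, written once in the text, reaches both states;
the negation 无 scopes only the second. The compound pulse 脉弦细弱
(`symnorm.fixtures.compound_pulse`) normalizes to three rows pairing 脉
with 弦, 细 and 弱. The scripts in `examples/` walk through each
capability (validation, extraction, normalization, synthesis,
evaluation, tagging) with printed output.

The same pipeline from the shell:

```sh
symnorm synth --n 500 --seed 42 -o synth.jsonl
symnorm extract-relations synth.jsonl -o pred.jsonl
symnorm normalize pred.jsonl -o rows.tsv
symnorm evaluate --gold synth.jsonl --pred pred.jsonl --level relations --per-type
```

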