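# Methods

## The annotation model

Symptom descriptions in TCM present-illness narratives are decomposed
along the **position + state** axis. A symptom element that can stand
alone is a `Symp_S`; one that cannot (疼痛 "pain", 弦 "stringy") is a
`State` and combines with a position. The position itself splits into a
primary subject (`Pos_Pri`: anatomy, organ, mental activity, 下肢/脉/口),
an optional scope qualifier restricting its range (`Pos_SCP`: 左/右/双),
and an optional subordinate aspect between primary and state
(`Pos_Sub`: quantity, colour, quality, e.g. 质 in 痰质稠). Seven
modifier types carry the clinical context that coarse-grained schemes
drop: onset `Time` of a symptom group, `Neg`ation, triggering
`Cond`ition, `Freq`uency, qualitative and quantitative severity
(`Sev_Qual`, `Sev_Quant`), and `Trend` (aggravation/relief).

Ten directed relations connect these, named `subject_object`. The
endpoint constraint matrix is fixed (see
`symnorm.schema.RELATION_CONSTRAINTS`); notably `SPri` admits both
`State` and `Pos_Sub` subjects (progressive annotation
subordinate → primary → scope), while all modifier relations take a
`State` or `Symp_S` subject.

Annotation principles are enforced as data-level validity checks, not
constructor exceptions: no overlapping spans, no nesting, offsets that
match the text, unique (start, end, label) triples, unique relation
triples, constraint-matrix conformance. `validate_document` returns
every violation with its location; an entity containing a clause
delimiter is only a warning (such spans occur in free text but merit
review). Offsets are 0-based half-open counts of Unicode code points,
matching the annotation tool's JSONL export and keeping Chinese
characters atomic.

### Segmentation

Clauses are bounded by the full-width comma "，" and period "。";
sentences by "。" alone. The enumeration mark "、" and semicolons are
deliberately **not** delimiters: negation scopes like 无咳嗽、发热 must
run across the enumeration. Both sets are configurable
(`SegmentationConfig`), with the invariant that sentence delimiters are
a subset of clause delimiters.

## Rule-based relation extraction

Five deterministic procedures, each anchored on one entity family
(`symnorm.rules`). Where the published formulation leaves a scan bound
open, the default is the narrowest reading that still supports the
observed sharing behaviour, and each bound is a flag on `RuleConfig`:

* **Rule 1 bound** — the leftward position scan for a state crosses
  "，" (a primary written once serves several states in later clauses)
  but stops at "。": cross-sentence position attachment is clinically
  implausible. The flanking-neighbour test uses the same sentence bound.
* **Rule 2 bound** — the scope's rightward search stays within its
  clause and skips intervening scopes, so stacked qualifiers
  (左右下肢) each attach to the same head.
* **Rule 4 measure** — a time's range starts at the entity's end and
  runs to the next time entity's start, crossing clause and sentence
  boundaries (a dated symptom group may span several sentences).
* **Subordinate chaining** — the five rules as printed never emit
  `SPri` with a `Pos_Sub` subject, although gold corpora contain them
  via progressive annotation. `chain_subordinate_to_primary` adds the
  link (nearest primary leftward in the sentence, else rightward); it
  is **off** by default to stay faithful to the printed rules.

Extraction replaces any pre-existing relations rather than merging;
keeping gold alongside predictions is the caller's concern. The output
is deduplicated on (subject, object, type), independent of entity input
order, and always passes `validate_document`.

## Normalization

One row per symptom root per position path. Paths follow the position
relations depth-first from the root with a visited set (defensive
against cyclic annotations); each branch point multiplies paths, e.g. a
state annotated against two primaries yields two rows. Attribute texts
are collected per relation type and joined with ";" in document order
when repeated. Design choices where the published procedure is silent:

* a root with no position relations emits one bare row (its position
  columns "-") — standalone symptoms are normalized too;
* a path lacking a primary still emits its partial path;
* negation is a text column (the `Neg` surface form), not a boolean,
  preserving surface fidelity (无 vs 未见);
* identical rows arising from redundant gold relations are **not**
  deduplicated;
* the output is TSV, because cell values may contain "，".

## Evaluation

Strict criterion throughout: an entity is correct only if boundaries
and type both match; a relation only if both endpoint entity keys and
the type match. Micro scores pool keys over documents (and are
therefore invariant to how the corpus is partitioned); per-type scores
condition on the entity or relation label. Zero-denominator convention:
P = 0 when the prediction set is empty, R = 0 when the reference set is
empty, F₁ = 0 when P + R = 0. Pairwise inter-annotator agreement is the
same computation with one annotator as reference; since
|y¹∩y²| is symmetric, swapping annotators swaps P and R and leaves F₁
unchanged — a property the tests check against a brute-force
set-intersection oracle.

The annotation-rate (symptom-information-utilization) metric cuts each
document into sentence regions, each running through its terminating
delimiter, so delimiters count in the denominator; the corpus value is
the unweighted mean over sentences. On the worked example
6年前双下肢疼痛，无肿胀。 11 of 13 code points fall inside entity spans
(only "，" and "。" are uncovered), giving 11/13 ≈ 0.846.

## Synthetic corpus generator

Real annotated records are unavailable (patient privacy), so the
generator emulates their structure: sentences of "，"-joined clauses,
each clause either `[Cond?][Neg?][Pos_SCP{0..2}][Pos_Pri][Pos_Sub?]
[State][Freq?][Sev_Qual?][Sev_Quant?][Trend?]` or
`[Cond?][Neg?][Symp_S][attrs]`, with an optional `Time` prefixed to a
sentence. Gold relations come from the generation trace — which
position a state was built on, which negation governs it, which time
span covers it — never from running the extractor, so the clean-mode
equivalence test (extractor vs gold, micro F₁ = 1.0 over 1,000
documents) is a genuine oracle check, not a tautology.

Two structural notes:

* a clause emitting a `Pos_Sub` terminates its sentence. Without this,
  a clause-final state flanked by its subordinate (left) and the next
  clause's primary (right) would trigger the flanking-primary case of
  rule 1 while the construction intends the subordinate attachment;
  the generator's job in clean mode is to produce only configurations
  whose intended semantics the rules express.
* stacked scopes are the generator's only branch source: with
  `p_second_scope = 0` every root yields exactly one normalized row.

Default emission probabilities were chosen once to echo the published
corpus composition: `Symp_S` ≈ 18 % of symptom roots, scope on ≈ 18 %
and subordinate on ≈ 8.5 % of positional clauses, negation on ≈ 20 % of
clauses, a time on 60 % of sentences, attribute rates between 1.5 %
(quantitative severity, the rarest) and 7 %. Documents default to 2–4
sentences of 1–3 clauses. The built-in Chinese lexicon uses surface
forms typical of such narratives and is prefix-free (no entry is a
prefix of another), which makes greedy longest-match tagging recover
generated tokens exactly; an ASCII lexicon is available for debugging.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: typos and grammatical noise, discontinuous
or ambiguous position references, attribute co-occurrence structure,
long free-text modifiers (real trend descriptions run to 141
characters), and the length/type distribution of any particular
hospital's records. Adversarial mode reintroduces a slice of this
difficulty with labelled perturbations (an attribute moved past its
clause delimiter, a state written before its position, a negation
displaced behind its symptom) while gold keeps the intended semantics,
so rule degradation is measurable rather than assumed.

## Dictionary tagger

A greedy longest-match scan over a typed surface dictionary, mirroring
the maximize-coverage principle (手小指 beats 手 in 左手小指疼痛). One
surface maps to one type; conflicts are rejected at load. No dynamic
programming — the tagger is a pipeline baseline, not a recognizer;
trained sequence models are out of scope here.

## Published reference statistics

`symnorm.gdtcm500` records the public corpus-level tallies of the
GDTCM-500 annotation study (per-type entity/relation counts and
percentage shares, and the cross-scheme symptom-information-utilization
comparison). They are inputs for consistency arithmetic — totals,
recomputed shares, and the utilization lead over the best prior
scheme — recomputed at run time by `scripts/acceptance.py`, never
asserted as stored results.

## Problem sizes and numerics

The test suite and the acceptance script use 1,000-document synthetic
corpora for the oracle-equivalence and round-trip checks and 20–200
documents for property sweeps; at these sizes the full pipeline runs in
seconds. All randomness flows from explicit integer seeds (per-document
streams derived as `seed·1000003 + index`), so corpora are reproducible
bit-for-bit. Scores are exact rational arithmetic in floating point
(counts divided once); no tolerances beyond float equality are needed
for the invariance properties.

## Known limitations

* The rules encode the narrow-bound readings above; corpora annotated
  under broader conventions (cross-sentence position sharing) need the
  corresponding flags.
* Trend-like modifiers with weak positional regularity are exactly the
  cases the clause-scoped rule misses; the adversarial generator makes
  this visible but the package offers no learned fallback.
* Surface-to-terminology mapping (standardizing 弦 to a pulse-quality
  code) is future standardization work, out of scope.
* The strict scorer offers no partial-credit or kappa-style agreement.
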