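"""Normalize annotated narratives into standardized symptom rows.

Every State/Symp_S root becomes one row per position path; attribute
relations fill the time/negation/condition/... columns; "-" marks an
absent value.
"""

from symnorm import NORMALIZED_COLUMNS, normalize_document
from symnorm.fixtures import compound_pulse, lower_limb_pain

print("\t".join(NORMALIZED_COLUMNS))
for doc in (lower_limb_pain(), compound_pulse()):
    for row in normalize_document(doc):
        print("\t".join(row.as_cells()))
# The compound pulse description 脉弦细弱 unfolds into three rows —
# stringy pulse, thready pulse, weak pulse — resolving the symptom
# nesting that a coarse-grained annotation cannot split; the lower-limb
# narrative yields two rows sharing time 6年前 and position 双/下肢,
# the second carrying the negation 无.
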