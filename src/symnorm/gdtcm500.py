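"""Published summary statistics of the GDTCM-500 corpus.

GDTCM-500 is the annotated collection of 500 present-illness histories
from a Guangdong TCM hospital on which the fine-grained symptom schema
was developed.  The raw records are withheld for patient privacy; what
is public are the corpus-level tallies below — per-type entity and
relation annotation counts with their printed percentage shares, and
the cross-study comparison of symptom-information utilization
(TCM-SIU, the mean per-sentence fraction of characters covered by
annotations).  They serve as reference inputs for consistency checks:
the per-type counts must reproduce the printed totals and shares, and
the schema's TCM-SIU lead over the best prior scheme is their
difference.
"""

from __future__ import annotations

#: per-label entity annotation counts
ENTITY_COUNTS: dict[str, int] = {
    "State": 12584,
    "Pos_Pri": 11482,
    "Neg": 3097,
    "Symp_S": 2770,
    "Pos_SCP": 2230,
    "Time": 1991,
    "Pos_Sub": 1076,
    "Sev_Qual": 1043,
    "Freq": 988,
    "Cond": 893,
    "Trend": 719,
    "Sev_Quant": 224,
}

#: printed entity shares (%, two decimals as published)
ENTITY_PERCENTAGES: dict[str, float] = {
    "State": 32.20,
    "Pos_Pri": 29.40,
    "Neg": 7.90,
    "Symp_S": 7.10,
    "Pos_SCP": 5.70,
    "Time": 5.10,
    "Pos_Sub": 2.80,
    "Sev_Qual": 2.70,
    "Freq": 2.50,
    "Cond": 2.30,
    "Trend": 1.80,
    "Sev_Quant": 0.60,
}

#: published total number of annotated entities
ENTITY_TOTAL = 39097

#: per-label relation annotation counts
RELATION_COUNTS: dict[str, int] = {
    "STi": 15574,
    "SPri": 12361,
    "SN": 5185,
    "SSCP": 2295,
    "SC": 1564,
    "SF": 1199,
    "SSub": 1169,
    "SQual": 1156,
    "STr": 640,
    "SQuant": 230,
}

#: printed relation shares (%)
RELATION_PERCENTAGES: dict[str, float] = {
    "STi": 37.60,
    "SPri": 29.90,
    "SN": 12.50,
    "SSCP": 5.50,
    "SC": 3.80,
    "SF": 2.90,
    "SSub": 2.80,
    "SQual": 2.80,
    "STr": 1.50,
    "SQuant": 0.60,
}

#: published total number of annotated relation pairs
RELATION_TOTAL = 41373

#: TCM symptom-information utilization (%) by annotation scheme;
#: "fine_grained_12" is the 12-entity schema implemented here
TCM_SIU: dict[str, float] = {
    "gao_3_labels": 45.33,
    "zhang_13_labels": 20.21,
    "chang_7_labels": 62.43,
    "lee_3_labels": 50.86,
    "zou_9_labels": 59.64,
    "liu_4_labels": 42.01,
    "zhu_10_labels": 62.52,
    "fine_grained_12": 70.76,
}


def entity_count_sum() -> int:
    return sum(ENTITY_COUNTS.values())


def relation_count_sum() -> int:
    return sum(RELATION_COUNTS.values())


def entity_share_pct(label: str, ndigits: int = 1) -> float:
    """Share of one entity label recomputed from the counts, in percent."""
    return round(100.0 * ENTITY_COUNTS[label] / entity_count_sum(), ndigits)


def relation_share_pct(label: str, ndigits: int = 1) -> float:
    return round(100.0 * RELATION_COUNTS[label] / relation_count_sum(), ndigits)


def siu_improvement_pct() -> float:
    """Lead of the 12-entity schema's TCM-SIU over the best prior scheme."""
    ours = TCM_SIU["fine_grained_12"]
    best_prior = max(v for k, v in TCM_SIU.items() if k != "fine_grained_12")
    return round(ours - best_prior, 2)
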