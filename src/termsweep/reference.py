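"""Reference results from the 2018 survey of 81 U.S. breast cancer
organization websites (pages archived mid-November 2018; 14,087 kept URLs).

Each row gives, for one risk-factor group of the default lexicon: the
integer percent of the 81 organizations whose site mentioned the factor at
least once, the underlying organization count, and the total number of
mentions summed over all sites.  These are the published corpus-level
numbers the aggregation stage is designed to reproduce arithmetically
(percent from count) and structurally (table shape) — the underlying 2018
web content itself is not reproducible.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["SurveyRow", "N_SURVEY_ORGS", "SURVEY_TABLE", "HEADLINE_SHARES"]


class SurveyRow(NamedTuple):
    factor_name: str
    category: str
    pct_orgs_mentioning: int
    n_orgs_mentioning: int
    total_mentions: int


#: Total organizations surveyed.
N_SURVEY_ORGS = 81

#: Published per-factor prevalence, ordered as printed (descending percent).
SURVEY_TABLE: tuple[SurveyRow, ...] = (
    SurveyRow("Exercise", "other", 74, 60, 2796),
    SurveyRow("Family history", "other", 67, 54, 1167),
    SurveyRow("Diet", "other", 59, 48, 1514),
    SurveyRow("Genetics", "other", 52, 42, 1257),
    SurveyRow("Alcohol", "other", 48, 39, 722),
    SurveyRow("Breast density", "other", 44, 36, 542),
    SurveyRow("Body weight", "other", 36, 29, 456),
    SurveyRow("Hormone replacement therapy", "other", 30, 24, 800),
    SurveyRow("Pesticides", "specific_environmental", 30, 24, 565),
    SurveyRow("Bisphenols", "specific_environmental", 25, 20, 1582),
    SurveyRow("Contamination", "general_environmental", 25, 20, 517),
    SurveyRow("Pollution", "general_environmental", 25, 20, 644),
    SurveyRow("Birth control", "other", 23, 19, 398),
    SurveyRow("Parabens", "specific_environmental", 23, 19, 419),
    SurveyRow("Endocrine disrupting chemicals", "specific_environmental", 21, 17, 382),
    SurveyRow("Phthalates", "specific_environmental", 17, 14, 546),
    SurveyRow("Diethylstilbestrol", "other", 16, 13, 253),
    SurveyRow("The precautionary principle", "general_environmental", 15, 12, 142),
    SurveyRow("Flame retardants", "specific_environmental", 12, 10, 1074),
    SurveyRow("Air pollution", "specific_environmental", 11, 9, 80),
    SurveyRow("Polycyclic aromatic hydrocarbons", "specific_environmental", 11, 9, 104),
    SurveyRow("PFAS", "specific_environmental", 11, 9, 230),
    SurveyRow("Oxybenzone", "specific_environmental", 7, 6, 18),
)

#: Published headline shares: percent of organizations with at least one
#: general-environmental / specific-environmental / other-factor mention.
HEADLINE_SHARES = {
    "pct_general_env": 31,
    "pct_specific_env": 40,
    "pct_other": 82,
}
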