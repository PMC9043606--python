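"""Published aggregate counts from the Swiss community-based diabetes cohort
that this package's defaults emulate (baseline survey; 1033 respondents, 550
with complete visit data, four healthcare-use profiles).

These are *inputs*: per-profile counts of selected participant
characteristics as printed in the study's descriptive table, used to
re-derive percentages with nonmissing denominators and the sex-by-profile
chi-square test, and to reconstruct the complete-case exclusion
bookkeeping. Where a variable's per-profile counts sum to less than the
profile size, the remainder are missing values, exactly as in the source
table's denominators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ROSTER_TOTAL",
    "ANALYZED_TOTAL",
    "PROFILE_SIZES",
    "SEX_COUNTS",
    "build_characteristics_cohort",
    "build_exclusion_roster",
]

ROSTER_TOTAL = 1033
ANALYZED_TOTAL = 550

#: profile order: GP & podiatrist, GP only, High users, Diabetologist first
PROFILE_SIZES = (86, 195, 96, 173)

#: per-profile counts (rows = levels, columns = the four profiles)
SEX_COUNTS = {"female": (42, 62, 49, 77), "male": (44, 133, 47, 96)}
DIABETES_TYPE_COUNTS = {
    "type1": (7, 5, 18, 46),
    "type2": (69, 145, 73, 108),
    "other_unknown": (10, 45, 5, 19),
}
DURATION_COUNTS = {"1-10y": (33, 121, 47, 66), ">10y": (52, 71, 49, 106)}
INJECTABLE_COUNTS = {"no": (31, 151, 24, 49), "yes": (54, 44, 72, 123)}
HOSPITALIZATION_COUNTS = {
    "none": (66, 154, 60, 135),
    "once": (11, 32, 17, 25),
    "more_than_once": (9, 8, 16, 10),
}

_VARIABLES = {
    "sex": SEX_COUNTS,
    "diabetes_type": DIABETES_TYPE_COUNTS,
    "diabetes_duration": DURATION_COUNTS,
    "injectable_medication": INJECTABLE_COUNTS,
    "hospitalizations": HOSPITALIZATION_COUNTS,
}


def _expand(counts: dict[str, tuple], profile: int, size: int) -> list:
    """Level values for one profile, padded with missing to the profile size."""
    vals: list = []
    for level, per_profile in counts.items():
        vals.extend([level] * per_profile[profile])
    if len(vals) > size:
        raise ValueError("counts exceed profile size")
    vals.extend([None] * (size - len(vals)))
    return vals


def build_characteristics_cohort() -> tuple[CohortTable, np.ndarray]:
    """Reconstruct a 550-record cohort carrying exactly the printed
    per-profile counts of selected characteristics (other columns absent),
    plus the profile label vector. Within each profile, records with a
    missing value for a given variable are the trailing ones; since the
    descriptive machinery only uses counts, the within-profile arrangement
    is immaterial."""
    labels = np.repeat(np.arange(1, 5), PROFILE_SIZES)
    df = pd.DataFrame({"id": [f"R{i:04d}" for i in range(ANALYZED_TOTAL)]})
    for var, counts in _VARIABLES.items():
        col: list = []
        for p, size in enumerate(PROFILE_SIZES):
            col.extend(_expand(counts, p, size))
        df[var] = pd.Categorical(col, categories=list(counts))
    return CohortTable(df), labels


def build_exclusion_roster() -> CohortTable:
    """A 1033-record roster of which exactly 550 have complete visit data:
    the bookkeeping behind the study's complete-case clustering sample."""
    n = ROSTER_TOTAL
    complete = np.zeros(n, dtype=bool)
    complete[:ANALYZED_TOTAL] = True
    df = pd.DataFrame({"id": [f"Q{i:04d}" for i in range(n)]})
    visit_cols = [
        "visit_gp", "visit_diabetologist", "visit_diabetes_nurse",
        "visit_dietitian", "visit_podiatrist", "visit_emergency",
    ]
    for j, col in enumerate(visit_cols):
        vals = np.where(complete, "once", "once").astype(object)
        df[col] = pd.Categorical(vals, categories=["never", "once", "2-3", "4+"])
    # every excluded record is missing at least the GP answer
    df.loc[~complete, "visit_gp"] = np.nan
    return CohortTable(df)
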