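"""Column schema for the participant-level cohort table.

The schema is defined once, in ``data_dictionary.json`` (shipped with the
package), and loaded here. Every column has a role: ``identifier``, the six
ordinal ``visit`` variables used for clustering, sociodemographic and
diabetes ``covariate`` columns, binary ``process``-of-care indicators, and
continuous or binary ``outcome`` scores.
"""

from __future__ import annotations

import enum
import json
from importlib import resources
from typing import Any


class VisitLevel(enum.IntEnum):
    """Ordinal response category for a visit-frequency question.

    Exactly four levels, totally ordered; the integer value encodes the
    order only, not the pseudo-count (see :mod:`careprofiles.cohort` for
    the coding schemes).
    """

    NEVER = 0
    ONCE = 1
    TWO_THREE = 2
    FOUR_PLUS = 3

    @property
    def token(self) -> str:
        return _LEVEL_TOKENS[self]

    @classmethod
    def from_token(cls, token: str) -> "VisitLevel":
        """Parse a CSV token (case-insensitive) into a level."""
        key = token.strip().lower()
        try:
            return _TOKEN_LEVELS[key]
        except KeyError:
            raise ValueError(
                f"unknown visit level {token!r}; expected one of "
                f"{sorted(set(_TOKEN_LEVELS))}"
            ) from None


_LEVEL_TOKENS = {
    VisitLevel.NEVER: "never",
    VisitLevel.ONCE: "once",
    VisitLevel.TWO_THREE: "2-3",
    VisitLevel.FOUR_PLUS: "4+",
}

# Accept a few synonymous spellings on input; serialize with the canonical
# tokens above.
_TOKEN_LEVELS = {
    "never": VisitLevel.NEVER,
    "once": VisitLevel.ONCE,
    "2-3": VisitLevel.TWO_THREE,
    "2-3 times": VisitLevel.TWO_THREE,
    "two_three": VisitLevel.TWO_THREE,
    "4+": VisitLevel.FOUR_PLUS,
    "4 times and more": VisitLevel.FOUR_PLUS,
    "4 times or more": VisitLevel.FOUR_PLUS,
    "four_plus": VisitLevel.FOUR_PLUS,
}

VISIT_TOKENS = tuple(_LEVEL_TOKENS[lv] for lv in VisitLevel)


def load_data_dictionary() -> dict[str, dict[str, Any]]:
    """Load the machine-readable data dictionary shipped with the package."""
    text = resources.files("careprofiles").joinpath("data_dictionary.json").read_text()
    return json.loads(text)


DATA_DICTIONARY = load_data_dictionary()

ID_COLUMN = "id"

#: Fixed provider order for the clustering matrix.
VISIT_COLUMNS = (
    "visit_gp",
    "visit_diabetologist",
    "visit_diabetes_nurse",
    "visit_dietitian",
    "visit_podiatrist",
    "visit_emergency",
)

PROVIDERS = tuple(c.removeprefix("visit_") for c in VISIT_COLUMNS)

COVARIATE_COLUMNS = tuple(
    c for c, meta in DATA_DICTIONARY.items() if meta["role"] == "covariate"
)
PROCESS_COLUMNS = tuple(
    c for c, meta in DATA_DICTIONARY.items() if meta["role"] == "process"
)
OUTCOME_COLUMNS = tuple(
    c for c, meta in DATA_DICTIONARY.items() if meta["role"] == "outcome"
)

#: The five processes entering the five-process composites.
FIVE_PROCESSES = (
    "eye_exam_24m",
    "foot_exam",
    "microalbuminuria",
    "cholesterol",
    "flu_shot",
)
#: The six-process composites add repeated HbA1c measurement.
SIX_PROCESSES = FIVE_PROCESSES + ("hba1c_twice",)

COMPOSITE_COLUMNS = (
    "composite_ge4of5",
    "composite_all5",
    "composite_ge5of6",
    "composite_all6",
)

ALL_COLUMNS = (ID_COLUMN,) + VISIT_COLUMNS + COVARIATE_COLUMNS + PROCESS_COLUMNS + OUTCOME_COLUMNS

CATEGORICAL_LEVELS = {
    c: tuple(meta["levels"])
    for c, meta in DATA_DICTIONARY.items()
    if meta["dtype"] == "categorical"
}

FLOAT_COLUMNS = tuple(
    c for c, meta in DATA_DICTIONARY.items() if meta["dtype"] == "float"
)
INT_COLUMNS = tuple(c for c, meta in DATA_DICTIONARY.items() if meta["dtype"] == "int")
BINARY_COLUMNS = tuple(
    c for c, meta in DATA_DICTIONARY.items() if meta["dtype"] == "binary"
)
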