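"""Participant-level cohort table: CSV I/O, complete-case filter, ordinal
coding, composite quality indicators, and descriptive cross-tabulations.

The cohort is a flat table of one record per participant. The six visit
variables are ordinal with four levels (never / once / 2-3 / 4+); a
:class:`CodingScheme` maps them to pseudo-counts so a Poisson mixture can be
fitted. Missing values are empty CSV cells throughout; no imputation is ever
performed — each downstream model does its own complete-case restriction.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import schema
from .schema import (
    ALL_COLUMNS,
    BINARY_COLUMNS,
    CATEGORICAL_LEVELS,
    COMPOSITE_COLUMNS,
    FIVE_PROCESSES,
    FLOAT_COLUMNS,
    ID_COLUMN,
    INT_COLUMNS,
    SIX_PROCESSES,
    VISIT_COLUMNS,
    VisitLevel,
)

__all__ = [
    "CodingScheme",
    "CohortTable",
    "CompositeIndicators",
    "get_scheme",
    "read_cohort",
    "write_cohort",
    "filter_clustering_complete",
    "encode_visits",
    "derive_composites",
    "add_composites",
    "crosstab_percent",
    "round_half_up",
]


# ---------------------------------------------------------------------------
# Coding schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingScheme:
    """Map from the four ordinal visit levels to pseudo-counts.

    ``primary`` and ``sensitivity`` map to integers (required by the Poisson
    likelihood); ``plot_means`` is used only for descriptive mean-visit
    summaries, where the middle category is scored at its interval midpoint.
    """

    name: str
    mapping: Mapping[VisitLevel, float]

    def encode(self, levels: Iterable[VisitLevel]) -> np.ndarray:
        return np.array([self.mapping[lv] for lv in levels])

    @property
    def is_integer(self) -> bool:
        return all(float(v).is_integer() for v in self.mapping.values())


_SCHEMES = {
    "primary": CodingScheme(
        "primary",
        {
            VisitLevel.NEVER: 0,
            VisitLevel.ONCE: 1,
            VisitLevel.TWO_THREE: 2,
            VisitLevel.FOUR_PLUS: 4,
        },
    ),
    "sensitivity": CodingScheme(
        "sensitivity",
        {
            VisitLevel.NEVER: 0,
            VisitLevel.ONCE: 1,
            VisitLevel.TWO_THREE: 3,
            VisitLevel.FOUR_PLUS: 4,
        },
    ),
    "plot_means": CodingScheme(
        "plot_means",
        {
            VisitLevel.NEVER: 0.0,
            VisitLevel.ONCE: 1.0,
            VisitLevel.TWO_THREE: 2.5,
            VisitLevel.FOUR_PLUS: 4.0,
        },
    ),
}


def get_scheme(name: str) -> CodingScheme:
    """Return the named coding scheme (``primary``/``sensitivity``/``plot_means``)."""
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown coding scheme {name!r}; expected one of {sorted(_SCHEMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Ordered collection of participant records with provenance metadata.

    Wraps a :class:`pandas.DataFrame` whose columns follow the package data
    dictionary. Visit columns are ordered categoricals over the tokens
    ``never < once < 2-3 < 4+``; missing values are ``NaN``/``pd.NA``.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        ids = self.df[ID_COLUMN]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate participant id {dup!r}")

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.provenance))


_VISIT_DTYPE = pd.CategoricalDtype(categories=list(schema.VISIT_TOKENS), ordered=True)


def _parse_column(raw: pd.Series, col: str) -> pd.Series:
    """Parse one raw string column ("" = missing) to its schema dtype."""
    s = raw.replace("", pd.NA)
    if col in VISIT_COLUMNS:
        def norm(tok):
            if pd.isna(tok):
                return pd.NA
            return VisitLevel.from_token(str(tok)).token
        try:
            normed = s.map(norm)
        except ValueError:
            # re-run row-wise to name the offending cell
            for i, tok in s.items():
                if pd.isna(tok):
                    continue
                try:
                    VisitLevel.from_token(str(tok))
                except ValueError as exc:
                    raise ValueError(f"row {i}, column {col!r}: {exc}") from None
            raise
        return normed.astype(_VISIT_DTYPE)
    if col in CATEGORICAL_LEVELS:
        levels = CATEGORICAL_LEVELS[col]
        bad = s.dropna()[~s.dropna().isin(levels)]
        if len(bad):
            i = bad.index[0]
            raise ValueError(
                f"row {i}, column {col!r}: unknown category {bad.iloc[0]!r}; "
                f"expected one of {list(levels)}"
            )
        return s.astype(pd.CategoricalDtype(categories=list(levels)))
    if col in FLOAT_COLUMNS:
        try:
            return pd.to_numeric(s, errors="raise").astype(float)
        except (ValueError, TypeError):
            for i, tok in s.items():
                try:
                    if not pd.isna(tok):
                        float(tok)
                except ValueError:
                    raise ValueError(
                        f"row {i}, column {col!r}: cannot parse {tok!r} as a number"
                    ) from None
            raise
    if col in INT_COLUMNS or col in BINARY_COLUMNS:
        try:
            out = pd.to_numeric(s, errors="raise").astype("Int64")
        except (ValueError, TypeError):
            for i, tok in s.items():
                try:
                    if not pd.isna(tok):
                        int(tok)
                except ValueError:
                    raise ValueError(
                        f"row {i}, column {col!r}: cannot parse {tok!r} as an integer"
                    ) from None
            raise
        if col in BINARY_COLUMNS:
            bad = out.dropna()[~out.dropna().isin([0, 1])]
            if len(bad):
                raise ValueError(
                    f"row {bad.index[0]}, column {col!r}: binary indicator must be 0 or 1, "
                    f"got {bad.iloc[0]}"
                )
        return out
    return s.astype("string")


def read_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV (comma-separated, UTF-8, header required; "" = missing).

    With ``strict`` (default) any column outside the schema is rejected;
    otherwise extra columns are carried through untouched. Missing schema
    columns other than ``id`` are tolerated and created as all-missing.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in ALL_COLUMNS + COMPOSITE_COLUMNS]
    if unknown and strict:
        raise ValueError(
            f"unknown column(s) {unknown} in {path.name}; pass strict=False to permit"
        )
    if ID_COLUMN not in raw.columns:
        raise ValueError(f"{path.name} has no {ID_COLUMN!r} column")
    out = pd.DataFrame(index=raw.index)
    out[ID_COLUMN] = raw[ID_COLUMN].astype("string")
    for col in ALL_COLUMNS[1:] + COMPOSITE_COLUMNS:
        if col in raw.columns:
            out[col] = _parse_column(raw[col], col)
        elif col not in COMPOSITE_COLUMNS:
            out[col] = _parse_column(pd.Series([""] * len(raw), index=raw.index, dtype=str), col)
    for col in unknown:
        out[col] = raw[col].replace("", pd.NA)
    return CohortTable(out, provenance={"source": str(path)})


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to CSV with missing values as empty cells."""
    cohort.df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Complete-case filter and ordinal coding
# ---------------------------------------------------------------------------

def filter_clustering_complete(cohort: CohortTable) -> tuple[CohortTable, int]:
    """Drop records with any missing value among the six visit variables.

    Only the six clustering variables count; missing covariates or outcomes
    never exclude a record here. Order is preserved. Returns the kept cohort
    and the number excluded.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    visits = cohort.df[list(VISIT_COLUMNS)]
    keep = visits.notna().all(axis=1)
    kept = CohortTable(
        cohort.df.loc[keep].reset_index(drop=True),
        {**cohort.provenance, "complete_case_filter": "six visit variables"},
    )
    return kept, int((~keep).sum())


def encode_visits(cohort: CohortTable, scheme: CodingScheme | str) -> np.ndarray:
    """Encode the six visit columns as an n×6 pseudo-count matrix.

    Column order is fixed: GP, diabetologist, diabetes nurse, dietitian,
    podiatrist, emergency. Requires complete visit data (apply
    :func:`filter_clustering_complete` first).
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    visits = cohort.df[list(VISIT_COLUMNS)]
    if visits.isna().any().any():
        col = visits.columns[visits.isna().any()][0]
        raise ValueError(
            f"missing visit level in column {col!r}: apply filter_clustering_complete first"
        )
    token_map = {lv.token: scheme.mapping[lv] for lv in VisitLevel}
    mat = np.column_stack(
        [visits[c].astype(object).map(token_map).to_numpy(dtype=float) for c in VISIT_COLUMNS]
    )
    if scheme.is_integer:
        return mat.astype(np.int64)
    return mat


# ---------------------------------------------------------------------------
# Composite quality indicators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositeIndicators:
    """Binary composites over the process-of-care indicators.

    The five-process composites cover eye exam, foot exam, microalbuminuria,
    cholesterol and influenza shot; the six-process composites add repeated
    HbA1c measurement and are defined only for participants who know what
    HbA1c is. ``None`` means missing/undefined.
    """

    at_least_4_of_5: Optional[int]
    all_5: Optional[int]
    at_least_5_of_6: Optional[int]
    all_6: Optional[int]


def _threshold_composite(values: Sequence, k: int) -> Optional[int]:
    """1 if at least k of the components are yes, deciding under partial
    missingness whenever the observed components already force the answer."""
    n_yes = sum(1 for v in values if not pd.isna(v) and int(v) == 1)
    n_miss = sum(1 for v in values if pd.isna(v))
    if n_yes >= k:
        return 1
    if n_yes + n_miss < k:
        return 0
    return None


def derive_composites(record: Mapping) -> CompositeIndicators:
    """Compute the four composite indicators for one participant record.

    A composite with missing components is still reported when its value is
    already decidable from the observed ones (e.g. four observed "yes" out
    of five force the ≥4-of-5 composite to 1); otherwise it is missing.
    """
    five = [record.get(c) for c in FIVE_PROCESSES]
    ge4 = _threshold_composite(five, 4)
    all5 = _threshold_composite(five, 5)
    knows = record.get("knows_hba1c")
    if pd.isna(knows) or str(knows) != "yes":
        ge5 = all6 = None
    else:
        six = [record.get(c) for c in SIX_PROCESSES]
        ge5 = _threshold_composite(six, 5)
        all6 = _threshold_composite(six, 6)
    return CompositeIndicators(ge4, all5, ge5, all6)


def add_composites(cohort: CohortTable) -> CohortTable:
    """Append composite columns (composite_ge4of5, composite_all5,
    composite_ge5of6, composite_all6) to a copy of the cohort."""
    rows = [derive_composites(rec) for rec in cohort.df.to_dict("records")]
    out = cohort.df.copy()
    out["composite_ge4of5"] = pd.array([r.at_least_4_of_5 for r in rows], dtype="Int64")
    out["composite_all5"] = pd.array([r.all_5 for r in rows], dtype="Int64")
    out["composite_ge5of6"] = pd.array([r.at_least_5_of_6 for r in rows], dtype="Int64")
    out["composite_all6"] = pd.array([r.all_6 for r in rows], dtype="Int64")
    return CohortTable(out, dict(cohort.provenance))


# ---------------------------------------------------------------------------
# Descriptive cross-tabulations
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (presentation convention for tables)."""
    if pd.isna(x):
        return float("nan")
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def crosstab_percent(
    cohort: CohortTable,
    variable: str,
    by: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Counts and percentages of a categorical variable, overall and by group.

    Percentages use the per-group nonmissing count of the variable as
    denominator (so rows with missing values never dilute the percentages),
    rounded half-up to one decimal. ``by`` is an optional group label per
    record; an ``overall`` column is always included. A group where every
    value is missing gets counts 0 and undefined (NaN) percentages.
    """
    if variable not in cohort.df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    values = cohort.df[variable]
    if isinstance(values.dtype, pd.CategoricalDtype):
        levels = list(values.cat.categories)
    else:
        levels = sorted(values.dropna().unique().tolist())
    groups: list = ["overall"]
    membership = {"overall": pd.Series(True, index=values.index)}
    if by is not None:
        by = pd.Series(list(by), index=values.index)
        if len(by) != len(values):
            raise ValueError("group labels do not align with cohort records")
        for g in pd.unique(by.dropna()):
            groups.append(g)
            membership[g] = by == g
    cols = {}
    for g in groups:
        sub = values[membership[g]]
        denom = int(sub.notna().sum())
        counts = [int((sub == lv).sum()) for lv in levels]
        pcts = [
            round_half_up(100.0 * c / denom) if denom > 0 else float("nan")
            for c in counts
        ]
        cols[(g, "n")] = counts
        cols[(g, "pct")] = pcts
    out = pd.DataFrame(cols, index=pd.Index(levels, name=variable))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["group", "stat"])
    return out
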