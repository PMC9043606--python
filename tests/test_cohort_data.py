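"""Cohort table I/O, complete-case filter, ordinal coding, composites and
descriptive cross-tabulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import careprofiles as cp
from careprofiles.cohort import round_half_up
from careprofiles.schema import FIVE_PROCESSES, VISIT_COLUMNS, VisitLevel

CSV_SMALL = """id,visit_gp,visit_diabetologist,visit_diabetes_nurse,visit_dietitian,visit_podiatrist,visit_emergency,sex,age,sf12_pcs
A,never,once,2-3,4+,never,once,male,64,41.5
B,once,,never,never,never,never,female,70,
C,4+,2-3,once,never,2-3,never,male,55,50.0
"""


def test_read_small_file_and_missingness(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(CSV_SMALL)
    cohort = cp.read_cohort(p)
    assert len(cohort) == 3
    # blank diabetologist cell of record B is retained as missing
    assert pd.isna(cohort.df.loc[1, "visit_diabetologist"])
    assert cohort.df.loc[1, "visit_gp"] == "once"
    assert pd.isna(cohort.df.loc[1, "sf12_pcs"])


def test_round_trip_identity(tmp_path, messy_cohort):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    cp.write_cohort(messy_cohort.cohort, p1)
    c1 = cp.read_cohort(p1)
    cp.write_cohort(c1, p2)
    c2 = cp.read_cohort(p2)
    pd.testing.assert_frame_equal(c1.df, c2.df)


def test_unknown_visit_token_names_cell(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(CSV_SMALL.replace("2-3,4+", "5 times,4+", 1))
    with pytest.raises(ValueError, match=r"visit_diabetes_nurse.*5 times|5 times"):
        cp.read_cohort(p)


def test_duplicate_id_rejected(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(CSV_SMALL.replace("\nB,", "\nA,"))
    with pytest.raises(ValueError, match="duplicate"):
        cp.read_cohort(p)


def test_unknown_column_strictness(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("id,visit_gp,shoe_size\nA,never,43\n")
    with pytest.raises(ValueError, match="shoe_size"):
        cp.read_cohort(p)
    cohort = cp.read_cohort(p, strict=False)
    assert cohort.df.loc[0, "shoe_size"] == "43"


def test_filter_scope_is_visits_only(messy_cohort):
    cohort = messy_cohort.cohort
    kept, n_excluded = cp.filter_clustering_complete(cohort)
    assert len(kept) + n_excluded == len(cohort)
    assert kept.df[list(VISIT_COLUMNS)].notna().all().all()
    # idempotent on its own output; outcome missingness never excludes
    kept2, n2 = cp.filter_clustering_complete(kept)
    assert n2 == 0 and len(kept2) == len(kept)


@pytest.mark.parametrize(
    "scheme,expected_codes,two_three_code",
    [("primary", {0, 1, 2, 4}, 2), ("sensitivity", {0, 1, 3, 4}, 3), ("plot_means", None, 2.5)],
)
def test_encode_visits_codes(clean_cohort, scheme, expected_codes, two_three_code):
    mat = cp.encode_visits(clean_cohort.cohort, scheme)
    if expected_codes is not None:
        assert set(np.unique(mat)) <= expected_codes
    assert cp.get_scheme(scheme).mapping[VisitLevel.TWO_THREE] == two_three_code


def test_encode_visits_requires_complete_data(messy_cohort):
    with pytest.raises(ValueError, match="filter_clustering_complete"):
        cp.encode_visits(messy_cohort.cohort, "primary")


def test_composites_corners():
    base = {c: 1 for c in FIVE_PROCESSES}
    full = cp.derive_composites({**base, "knows_hba1c": "yes", "hba1c_twice": 1})
    assert (full.at_least_4_of_5, full.all_5, full.at_least_5_of_6, full.all_6) == (1, 1, 1, 1)
    four = cp.derive_composites({**base, "flu_shot": 0, "knows_hba1c": "no"})
    assert four.at_least_4_of_5 == 1 and four.all_5 == 0
    # six-process composites undefined without HbA1c knowledge
    assert four.at_least_5_of_6 is None and four.all_6 is None
    # decidable under partial missingness: four observed yes force >=4-of-5
    part = cp.derive_composites({**base, "flu_shot": None})
    assert part.at_least_4_of_5 == 1 and part.all_5 is None


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.lists(st.sampled_from([0, 1, None]), min_size=6, max_size=6),
    st.integers(min_value=0, max_value=5),
)
def test_composites_monotone_in_processes(vals, flip):
    """Turning any process from no to yes never decreases any composite."""
    def rec(v):
        d = dict(zip(FIVE_PROCESSES + ("hba1c_twice",), v))
        d["knows_hba1c"] = "yes"
        return d

    lo = cp.derive_composites(rec(vals))
    if vals[flip] == 0:
        up_vals = list(vals)
        up_vals[flip] = 1
        hi = cp.derive_composites(rec(up_vals))
        for a, b in zip(
            (lo.at_least_4_of_5, lo.all_5, lo.at_least_5_of_6, lo.all_6),
            (hi.at_least_4_of_5, hi.all_5, hi.at_least_5_of_6, hi.all_6),
        ):
            if a is not None and b is not None:
                assert b >= a


def test_composite_implications(clean_cohort):
    wc = cp.add_composites(clean_cohort.cohort)
    df = wc.df
    both5 = df["composite_all5"].eq(1)
    assert df.loc[both5, "composite_ge4of5"].eq(1).all()
    both6 = df["composite_all6"].eq(1)
    assert df.loc[both6, "composite_ge5of6"].eq(1).all()
    unknown = df["knows_hba1c"] != "yes"
    assert df.loc[unknown, "composite_ge5of6"].isna().all()


def test_crosstab_nonmissing_denominators(clean_cohort):
    cohort = clean_cohort.cohort
    tab = cp.crosstab_percent(cohort, "sex")
    pct = tab[("overall", "pct")]
    assert abs(pct.sum() - 100.0) <= 0.1
    n = tab[("overall", "n")]
    assert n.sum() == cohort.df["sex"].notna().sum()
    with pytest.raises(ValueError, match="unknown variable"):
        cp.crosstab_percent(cohort, "not_a_column")


def test_crosstab_missing_excluded_from_denominator():
    df = pd.DataFrame(
        {
            "id": [str(i) for i in range(10)],
            "diabetes_duration": pd.Categorical(
                ["1-10y"] * 4 + [">10y"] * 4 + [None, None],
                categories=["1-10y", ">10y"],
            ),
        }
    )
    tab = cp.crosstab_percent(cp.CohortTable(df), "diabetes_duration")
    assert tab.loc["1-10y", ("overall", "pct")] == 50.0
    assert tab.loc["1-10y", ("overall", "n")] == 4


def test_crosstab_all_missing_group_degenerate():
    df = pd.DataFrame(
        {"id": ["a", "b", "c"], "sex": pd.Categorical([None, None, "male"],
                                                      categories=["female", "male"])}
    )
    tab = cp.crosstab_percent(cp.CohortTable(df), "sex", by=["g1", "g1", "g2"])
    assert tab.loc["male", ("g1", "n")] == 0
    assert np.isnan(tab.loc["male", ("g1", "pct")])


def test_round_half_up_presentation_rule():
    assert round_half_up(36.95) == 37.0
    assert round_half_up(58.18) == 58.2
    assert round_half_up(22.55) == 22.6
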