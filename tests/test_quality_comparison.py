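"""Bivariate tests, regression fits and predictive margins."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import careprofiles as cp
from careprofiles.compare import (
    AdjustmentSet,
    bootstrap_margins,
    compare_profiles,
    fit_linear,
    fit_logistic,
    kruskal_wallis,
    pearson_chi_square,
    predictive_margins,
)

# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def test_kruskal_wallis_hand_ranked_example():
    """Groups (1,2,3) vs (4,5,6): mid-rank computation gives H = 3.857, df=1."""
    r = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
    assert r.statistic == pytest.approx(3.857, abs=5e-4)
    assert r.df == 1 and r.n_used == 6


def test_kruskal_wallis_all_tied_convention():
    r = kruskal_wallis([7, 7, 7, 7], ["a", "a", "b", "b"])
    assert r.statistic == 0.0 and r.p_value == 1.0


def test_kruskal_wallis_drops_missing_pairs():
    r = kruskal_wallis([1, 2, None, 4, 5, 6], ["a", "a", "a", None, "b", "b"])
    assert r.n_used == 4


def test_kruskal_wallis_needs_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([1, 2, 3], ["a", "a", "a"])


def test_kruskal_wallis_monotone_invariance():
    rng = np.random.default_rng(0)
    v = rng.normal(size=30)
    g = rng.integers(0, 3, size=30)
    a = kruskal_wallis(v, g)
    b = kruskal_wallis(np.exp(v), g)  # strictly monotone transform
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_kruskal_wallis_p_against_permutation_oracle():
    """Chi-square approximation within ±0.005 of a 10^5-draw permutation null."""
    rng = np.random.default_rng(1)
    sizes = [15, 15, 15]
    values = np.concatenate(
        [rng.normal(0.0, 1, 15), rng.normal(0.6, 1, 15), rng.normal(1.0, 1, 15)]
    )
    groups = np.repeat(["a", "b", "c"], 15)
    res = kruskal_wallis(values, groups)

    from scipy.stats import rankdata

    ranks = rankdata(values)
    n = len(ranks)
    B = 100_000
    perm_rng = np.random.default_rng(7)
    perms = perm_rng.permuted(np.tile(ranks, (B, 1)), axis=1)
    h = np.zeros(B)
    start = 0
    for sz in sizes:
        h += perms[:, start:start + sz].sum(axis=1) ** 2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    p_perm = (h >= res.statistic - 1e-12).mean()
    assert res.p_value == pytest.approx(p_perm, abs=0.005)


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


def test_chi_square_direct_oe_arithmetic_oracle():
    rng = np.random.default_rng(2)
    t = rng.integers(5, 40, size=(3, 4)).astype(float)
    r = pearson_chi_square(t)
    expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
    x2 = ((t - expected) ** 2 / expected).sum()
    assert r.statistic == pytest.approx(x2, abs=1e-10)
    assert r.df == (3 - 1) * (4 - 1)


def test_chi_square_proportional_rows_zero():
    r = pearson_chi_square([[10, 20], [30, 60]])
    assert r.statistic == pytest.approx(0.0, abs=1e-10)


def test_chi_square_zero_margin_error():
    with pytest.raises(ValueError, match="row|column"):
        pearson_chi_square([[0, 0], [3, 4]])


def test_chi_square_permutation_invariance():
    t = np.array([[5, 9, 2], [7, 3, 8]])
    a = pearson_chi_square(t)
    b = pearson_chi_square(t[::-1, [2, 0, 1]])
    assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------


def _cohort_from(df):
    df = df.copy()
    df.insert(0, "id", [str(i) for i in range(len(df))])
    return cp.CohortTable(df)


def test_logistic_intercept_only_is_bernoulli_mle():
    y = [1] * 30 + [0] * 70
    data = _cohort_from(pd.DataFrame({"eye_exam_24m": pd.array(y, dtype="Int64")}))
    fit = fit_logistic("eye_exam_24m", [1] * 100, AdjustmentSet.crude(), data)
    m = predictive_margins(fit)
    assert m.table["estimate"].iloc[0] == pytest.approx(0.300, abs=1e-9)


def test_logistic_two_group_odds_ratio_closed_form():
    """Counts (20,80 / 40,60) → OR = (40/60)/(20/80) = 2.667."""
    y = [1] * 20 + [0] * 80 + [1] * 40 + [0] * 60
    labels = [1] * 100 + [2] * 100
    data = _cohort_from(pd.DataFrame({"foot_exam": pd.array(y, dtype="Int64")}))
    fit = fit_logistic("foot_exam", labels, AdjustmentSet.crude(), data)
    beta = dict(zip(fit.colnames, fit.params))["profile_2"]
    assert np.exp(beta) == pytest.approx(2.667, abs=5e-4)


def test_logistic_matches_independent_optimizer():
    """MLE agrees with a general-purpose optimizer of the same likelihood."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(3)
    n = 300
    labels = rng.integers(1, 4, size=n)
    age = rng.uniform(40, 80, size=n)
    compl = rng.poisson(0.8, size=n)
    eta = -2.0 + 0.4 * (labels == 2) + 0.03 * (age - 60) + 0.3 * compl
    y = (rng.random(n) < expit(eta)).astype(int)
    df = pd.DataFrame(
        {"bp_twice": pd.array(y, dtype="Int64"), "age": age, "n_complications": compl}
    )
    adjust = AdjustmentSet(("age", "n_complications"))
    fit = fit_logistic("bp_twice", labels, adjust, _cohort_from(df))

    X = np.column_stack(
        [np.ones(n)]
        + [(labels == g).astype(float) for g in fit.profile_levels if g != fit.ref_profile]
        + [age, compl]
    )

    def nll(beta):
        e = X @ beta
        return -(y * e - np.logaddexp(0, e)).sum()

    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
    assert np.allclose(fit.params, res.x, atol=1e-6)


def test_logistic_degenerate_response_rejected():
    data = _cohort_from(pd.DataFrame({"flu_shot": pd.array([1] * 20, dtype="Int64")}))
    with pytest.raises(ValueError, match="variation"):
        fit_logistic("flu_shot", [1] * 20, AdjustmentSet.crude(), data)


def test_linear_crude_fitted_values_are_group_means():
    rng = np.random.default_rng(4)
    y = rng.normal(size=90)
    labels = np.repeat([1, 2, 3], 30)
    data = _cohort_from(pd.DataFrame({"pacic": y}))
    fit = fit_linear("pacic", labels, AdjustmentSet.crude(), data)
    m = predictive_margins(fit)
    for g in (1, 2, 3):
        assert m.table.set_index("profile").loc[g, "estimate"] == pytest.approx(
            y[labels == g].mean(), abs=1e-12
        )


def test_linear_exact_fit_zero_residuals():
    age = np.linspace(30, 80, 60)
    y = 2.0 + 0.05 * age
    df = pd.DataFrame({"sf12_pcs": y, "age": age, "n_complications": np.zeros(60)})
    fit = fit_linear("sf12_pcs", [1] * 60, AdjustmentSet(("age",)), df.pipe(_cohort_from))
    X = np.column_stack([np.ones(60), age])
    resid = y - X @ fit.params
    assert np.max(np.abs(resid)) < 1e-10


def test_linear_matches_normal_equations():
    rng = np.random.default_rng(5)
    n = 200
    labels = rng.integers(1, 4, size=n)
    age = rng.uniform(30, 85, size=n)
    y = rng.normal(size=n) + 0.1 * age
    data = _cohort_from(pd.DataFrame({"addqol": y, "age": age}))
    fit = fit_linear("addqol", labels, AdjustmentSet(("age",)), data)
    X = np.column_stack(
        [np.ones(n)]
        + [(labels == g).astype(float) for g in fit.profile_levels if g != fit.ref_profile]
        + [age]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.params, beta, atol=1e-10)


def test_linear_rank_deficiency_names_columns():
    df = pd.DataFrame({"pacic": np.random.default_rng(6).normal(size=40),
                       "age": np.full(40, 50.0)})
    with pytest.raises(ValueError, match="collinear"):
        # constant age duplicates the intercept
        fit_linear("pacic", [1] * 40, AdjustmentSet(("age",)), _cohort_from(df))


# ---------------------------------------------------------------------------
# Predictive margins
# ---------------------------------------------------------------------------


def _margins_brute_force(fit):
    """Oracle: copy the data, overwrite the factor, average row predictions."""
    out = {}
    X_cols = fit.colnames
    df = fit._df_used
    for g in fit.profile_levels:
        preds = []
        for i in range(len(df)):
            x = []
            for c in X_cols:
                if c == "intercept":
                    x.append(1.0)
                elif c.startswith("profile_"):
                    x.append(1.0 if int(c.split("_")[1]) == g else 0.0)
                elif c in df.columns:
                    x.append(float(df[c].iloc[i]))
                else:  # categorical dummy "cov_level"
                    cov, lv = c.rsplit("_", 1)
                    # reconstruct from longest-prefix covariate name
                    while cov not in df.columns and "_" in cov:
                        cov, rest = cov.rsplit("_", 1)
                        lv = rest + "_" + lv
                    x.append(1.0 if str(df[cov].iloc[i]) == lv else 0.0)
            eta = float(np.dot(x, fit.params))
            preds.append(expit(eta) if fit.family == "logistic" else eta)
        out[g] = float(np.mean(preds))
    return out


def test_margins_match_overwrite_and_average_oracle(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    for response, fitter in (("foot_exam", fit_logistic), ("pacic", fit_linear)):
        fit = fitter(response, labels, AdjustmentSet.default(), kept)
        m = predictive_margins(fit)
        oracle = _margins_brute_force(fit)
        for _, row in m.table.iterrows():
            assert row["estimate"] == pytest.approx(oracle[int(row["profile"])], abs=1e-10)


def test_crude_saturated_margins_equal_group_proportions(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    fit = fit_logistic("eye_exam_24m", labels, AdjustmentSet.crude(), kept)
    m = predictive_margins(fit).table.set_index("profile")
    y = kept.df["eye_exam_24m"].to_numpy(dtype=float)
    for g in np.unique(labels):
        assert m.loc[g, "estimate"] == pytest.approx(y[labels == g].mean(), abs=1e-9)


def test_margins_average_to_overall_mean(labelled_cohort):
    """Share-weighted crude saturated margins reproduce the observed mean."""
    kept, _, _, labels = labelled_cohort
    for response, fitter in (("flu_shot", fit_logistic), ("sf12_mcs", fit_linear)):
        fit = fitter(response, labels, AdjustmentSet.crude(), kept)
        m = predictive_margins(fit).table.set_index("profile")
        y = kept.df[response].to_numpy(dtype=float)
        shares = {g: (labels == g).mean() for g in np.unique(labels)}
        combined = sum(shares[g] * m.loc[g, "estimate"] for g in shares)
        assert combined == pytest.approx(y.mean(), abs=1e-10)


def test_linear_crude_margin_cis_are_pooled_variance_group_cis():
    rng = np.random.default_rng(7)
    y = rng.normal(size=120)
    labels = np.repeat([1, 2, 3, 4], 30)
    data = _cohort_from(pd.DataFrame({"addqol": y}))
    fit = fit_linear("addqol", labels, AdjustmentSet.crude(), data)
    m = predictive_margins(fit).table.set_index("profile")
    resid = np.concatenate([y[labels == g] - y[labels == g].mean() for g in (1, 2, 3, 4)])
    s2 = (resid**2).sum() / (120 - 4)
    for g in (1, 2, 3, 4):
        assert m.loc[g, "se"] == pytest.approx(np.sqrt(s2 / 30), rel=1e-9)


def test_margin_for_absent_level_rejected(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    fit = fit_logistic("foot_exam", labels, AdjustmentSet.crude(), kept)
    with pytest.raises(ValueError, match="absent"):
        predictive_margins(fit, levels=[99])


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def test_compare_profiles_tables_complete(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    tables = compare_profiles(kept, labels, mode="crude")
    K = len(np.unique(labels))
    # 8 processes + 4 composites, one row per profile each
    assert len(tables["processes"]) == 12 * K
    assert len(tables["outcomes"]) == 7 * K
    ok = tables["processes"][~tables["processes"]["degenerate"]]
    assert ok["estimate"].between(0, 1).all()
    assert (ok["ci_low"] <= ok["estimate"]).all() and (ok["estimate"] <= ok["ci_high"]).all()
    assert set(tables["table1"]["test"]) == {"kruskal_wallis", "chi_square"}


def test_compare_profiles_flags_degenerate_indicator(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    const = kept.copy()
    const.df["flu_shot"] = 1
    tables = compare_profiles(const, labels, mode="crude", processes=["flu_shot"],
                              outcomes=["pacic"])
    assert tables["processes"]["degenerate"].all()
    assert not tables["outcomes"]["degenerate"].any()


def test_hba1c_rows_restricted_to_knowers(labelled_cohort):
    kept, _, _, labels = labelled_cohort
    tables = compare_profiles(kept, labels, mode="crude",
                              processes=["hba1c_twice", "foot_exam"], outcomes=[])
    t = tables["processes"]
    n_know = int((kept.df["knows_hba1c"] == "yes").sum())
    assert t[t["indicator"] == "hba1c_twice"]["n_used"].max() <= n_know
    assert t[t["indicator"] == "foot_exam"]["n_used"].max() <= len(kept)
    assert t[t["indicator"] == "foot_exam"]["n_used"].max() > n_know
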