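"""Comparison of characteristics and quality-of-care indicators across
healthcare-use profiles.

Bivariate screening uses the Kruskal–Wallis test for continuous variables
and Pearson's chi-square for categorical ones. Each binary process
indicator is then modelled by maximum-likelihood logistic regression and
each continuous outcome by least-squares linear regression, with the
profile as exposure factor, either crude or adjusted for age, sex, living
arrangement, residential location, education, insurance model, insurance
subsidies and number of diabetes-related complications. Profile-level
summaries are predictive margins (marginal standardization): the model
prediction averaged over the estimation sample with every record's profile
set to the level in question, with delta-method standard errors and normal
95% confidence intervals.

Every fit and test is complete-case for the variables it uses and reports
its n_used; no imputation, no multiple-testing adjustment (p-values are
raw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import CohortTable, add_composites
from .schema import CATEGORICAL_LEVELS, COMPOSITE_COLUMNS, PROCESS_COLUMNS

__all__ = [
    "BivariateTestResult",
    "AdjustmentSet",
    "RegressionFit",
    "MarginsResult",
    "kruskal_wallis",
    "pearson_chi_square",
    "fit_logistic",
    "fit_linear",
    "predictive_margins",
    "bootstrap_margins",
    "compare_profiles",
]

Z_95 = 1.959963984540054  # normal 97.5th percentile


@dataclass(frozen=True)
class BivariateTestResult:
    statistic: float
    df: int
    p_value: float
    n_used: int


def kruskal_wallis(values: Sequence, groups: Sequence) -> BivariateTestResult:
    """Kruskal–Wallis H over groups, mid-ranks with tie correction.

    Pairs with a missing value or group label are dropped first. When every
    retained value is identical the tie correction degenerates; by
    convention H = 0 (no between-group rank variation) with p = 1.
    """
    v = pd.Series(list(values), dtype="float64")
    g = pd.Series(list(groups))
    ok = v.notna() & g.notna()
    v, g = v[ok], g[ok]
    samples = [v[g == lvl].to_numpy() for lvl in pd.unique(g)]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with nonmissing values")
    df = len(samples) - 1
    n = int(sum(len(s) for s in samples))
    if np.all(v.to_numpy() == v.iloc[0]):
        return BivariateTestResult(0.0, df, 1.0, n)
    stat, p = scipy.stats.kruskal(*samples)
    return BivariateTestResult(float(stat), df, float(p), n)


def pearson_chi_square(table) -> BivariateTestResult:
    """Pearson chi-square on an r×c contingency table, no continuity
    correction; expected counts from the product of margins over the total."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-D")
    row_m, col_m = t.sum(axis=1), t.sum(axis=0)
    if np.any(row_m <= 0):
        raise ValueError(f"empty row {int(np.argmin(row_m))} in contingency table")
    if np.any(col_m <= 0):
        raise ValueError(f"empty column {int(np.argmin(col_m))} in contingency table")
    res = scipy.stats.chi2_contingency(t, correction=False)
    return BivariateTestResult(
        float(res.statistic), int(res.dof), float(res.pvalue), int(t.sum())
    )


# ---------------------------------------------------------------------------
# Regression models with the study adjustment set
# ---------------------------------------------------------------------------

#: covariates entered in every adjusted model; age and the complication
#: count are continuous, the rest reference-coded categories.
ADJUSTMENT_COVARIATES = (
    "age",
    "sex",
    "living_arrangement",
    "residential_location",
    "education",
    "insurance_model",
    "subsidies",
    "n_complications",
)
_CONTINUOUS_ADJUSTMENT = frozenset({"age", "n_complications"})


@dataclass(frozen=True)
class AdjustmentSet:
    """Covariates entering the linear predictor alongside the profile factor."""

    covariates: tuple = ()
    references: dict = field(default_factory=dict)

    @classmethod
    def crude(cls) -> "AdjustmentSet":
        return cls(())

    @classmethod
    def default(cls) -> "AdjustmentSet":
        return cls(ADJUSTMENT_COVARIATES)

    def reference_for(self, cov: str) -> str:
        return self.references.get(cov, CATEGORICAL_LEVELS[cov][0])


@dataclass
class RegressionFit:
    family: str  # "logistic" | "linear"
    params: np.ndarray
    cov_params: np.ndarray
    n_used: int
    colnames: list
    profile_levels: list
    ref_profile: int
    adjust: AdjustmentSet
    response: str
    scale: Optional[float]  # residual variance (linear) or None
    loglik: Optional[float]
    _df_used: pd.DataFrame = field(repr=False, default=None)
    _labels_used: np.ndarray = field(repr=False, default=None)
    _y_used: np.ndarray = field(repr=False, default=None)


def _design_matrix(
    df: pd.DataFrame,
    labels: np.ndarray,
    adjust: AdjustmentSet,
    profile_levels: Sequence[int],
    ref_profile: int,
    override_profile: Optional[int] = None,
) -> pd.DataFrame:
    n = len(df)
    lab = np.full(n, override_profile) if override_profile is not None else labels
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for g in profile_levels:
        if g != ref_profile:
            cols[f"profile_{g}"] = (lab == g).astype(float)
    for cov in adjust.covariates:
        if cov in _CONTINUOUS_ADJUSTMENT:
            cols[cov] = df[cov].to_numpy(dtype=float)
        else:
            ref = adjust.reference_for(cov)
            for lv in CATEGORICAL_LEVELS[cov]:
                if lv != ref:
                    cols[f"{cov}_{lv}"] = (df[cov] == lv).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _complete_cases(
    data: CohortTable, response: str, labels: Sequence, adjust: AdjustmentSet
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    df = data.df
    lab = pd.Series(list(labels), index=df.index)
    ok = df[response].notna() & lab.notna()
    for cov in adjust.covariates:
        ok &= df[cov].notna()
    sub = df.loc[ok]
    return sub, lab[ok].to_numpy(dtype=int), sub[response].to_numpy(dtype=float)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        names = [X.columns[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear column(s): {names}")


def _prepare(data, response, labels, adjust):
    sub, lab, y = _complete_cases(data, response, labels, adjust)
    if len(sub) == 0:
        raise ValueError(f"no complete cases for response {response!r}")
    levels = sorted(np.unique(lab).tolist())
    counts = pd.Series(lab).value_counts()
    # reference = largest profile (ties toward the smaller label)
    ref = int(counts[counts == counts.max()].index.min())
    X = _design_matrix(sub, lab, adjust, levels, ref)
    _check_rank(X)
    return sub, lab, y, X, levels, ref


def fit_logistic(
    response: str,
    labels: Sequence,
    adjust: AdjustmentSet,
    data: CohortTable,
) -> RegressionFit:
    """Maximum-likelihood logistic regression of a binary indicator on the
    profile factor plus the adjustment covariates (complete-case)."""
    sub, lab, y, X, levels, ref = _prepare(data, response, labels, adjust)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError(f"response {response!r} has no variation among complete cases")
    try:
        res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=100)
    except PerfectSeparationError as exc:
        raise RuntimeError(
            f"perfect separation while fitting {response!r}: {exc}"
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit for {response!r} did not converge")
    return RegressionFit(
        family="logistic",
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        n_used=len(y),
        colnames=list(X.columns),
        profile_levels=levels,
        ref_profile=ref,
        adjust=adjust,
        response=response,
        scale=None,
        loglik=float(res.llf),
        _df_used=sub,
        _labels_used=lab,
        _y_used=y,
    )


def fit_linear(
    response: str,
    labels: Sequence,
    adjust: AdjustmentSet,
    data: CohortTable,
) -> RegressionFit:
    """Least-squares linear regression, same design conventions as the
    logistic model; coefficient covariance is σ̂²(XᵀX)⁻¹ with σ̂² the
    residual mean square."""
    sub, lab, y, X, levels, ref = _prepare(data, response, labels, adjust)
    if len(y) < X.shape[1] + 1:
        raise ValueError(
            f"only {len(y)} complete cases for {X.shape[1]} design columns"
        )
    res = sm.OLS(y, X.to_numpy()).fit()
    return RegressionFit(
        family="linear",
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        n_used=len(y),
        colnames=list(X.columns),
        profile_levels=levels,
        ref_profile=ref,
        adjust=adjust,
        response=response,
        scale=float(res.scale),
        loglik=None,
        _df_used=sub,
        _labels_used=lab,
        _y_used=y,
    )


# ---------------------------------------------------------------------------
# Predictive margins
# ---------------------------------------------------------------------------

@dataclass
class MarginsResult:
    """Per-profile adjusted probability or mean with delta-method 95% CI."""

    outcome: str
    model: str  # "crude" | "adjusted"
    family: str
    table: pd.DataFrame  # columns: profile, estimate, se, ci_low, ci_high, n_used


def predictive_margins(fit: RegressionFit, levels: Optional[Sequence[int]] = None) -> MarginsResult:
    """Marginal standardization over the estimation sample.

    For each profile level g the whole sample's profile is set to g, the
    model prediction is averaged on the response scale, and the standard
    error follows by the delta method from the coefficient covariance.
    Logistic CIs are clipped to [0, 1].
    """
    levels = list(levels) if levels is not None else list(fit.profile_levels)
    for g in levels:
        if g not in fit.profile_levels:
            raise ValueError(f"profile level {g} absent from the fitted model")
    rows = []
    for g in levels:
        Xg = _design_matrix(
            fit._df_used, fit._labels_used, fit.adjust,
            fit.profile_levels, fit.ref_profile, override_profile=g,
        ).to_numpy()
        eta = Xg @ fit.params
        if fit.family == "logistic":
            p = expit(eta)
            m = float(p.mean())
            grad = (p * (1 - p)) @ Xg / len(p)
        else:
            m = float(eta.mean())
            grad = Xg.mean(axis=0)
        se = float(np.sqrt(grad @ fit.cov_params @ grad))
        lo, hi = m - Z_95 * se, m + Z_95 * se
        if fit.family == "logistic":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        rows.append(
            {"profile": g, "estimate": m, "se": se,
             "ci_low": lo, "ci_high": hi, "n_used": fit.n_used}
        )
    mode = "adjusted" if fit.adjust.covariates else "crude"
    return MarginsResult(fit.response, mode, fit.family, pd.DataFrame(rows))


def bootstrap_margins(
    response: str,
    labels: Sequence,
    adjust: AdjustmentSet,
    data: CohortTable,
    n_boot: int = 200,
    seed: int = 0,
    family: str = "logistic",
) -> pd.DataFrame:
    """Nonparametric bootstrap of the predictive margins (opt-in alternative
    to the delta method): resample records, refit, recompute margins.
    Returns per-profile mean and SD over successful replicates."""
    rng = np.random.default_rng(seed)
    fitter = fit_logistic if family == "logistic" else fit_linear
    base = fitter(response, labels, adjust, data)
    levels = base.profile_levels
    draws: dict[int, list[float]] = {g: [] for g in levels}
    n = len(data)
    lab_arr = np.asarray(list(labels))
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bdf = data.df.iloc[idx].reset_index(drop=True)
        bdf["id"] = [str(i) for i in range(n)]  # resampling duplicates ids
        boot = CohortTable(bdf, dict(data.provenance))
        try:
            f = fitter(response, lab_arr[idx], adjust, boot)
            m = predictive_margins(f, levels=[g for g in levels if g in f.profile_levels])
        except (ValueError, RuntimeError):
            continue
        for _, row in m.table.iterrows():
            draws[int(row["profile"])].append(float(row["estimate"]))
    rows = [
        {"profile": g, "boot_mean": float(np.mean(v)), "boot_sd": float(np.std(v, ddof=1)),
         "n_reps": len(v)}
        for g, v in draws.items() if len(v) >= 2
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report tables (figure/table analogs)
# ---------------------------------------------------------------------------

#: continuous outcomes modelled linearly; BP control is binary → logistic.
CONTINUOUS_OUTCOMES = ("sf12_pcs", "sf12_mcs", "addqol", "pacic", "self_efficacy", "hba1c_value")
_HBA1C_RESTRICTED = {"hba1c_twice", "composite_ge5of6", "composite_all6", "hba1c_value"}
_PHASE_2017_RESTRICTED = {"self_efficacy"}

#: Table-1-style covariates screened bivariately (continuous → KW, else chi-square).
_TABLE1_CONTINUOUS = ("age", "n_complications", "n_comorbidities")


def _restrict(cohort: CohortTable, labels: np.ndarray, indicator: str) -> tuple[CohortTable, np.ndarray]:
    df, lab = cohort.df, labels
    mask = pd.Series(True, index=df.index)
    if indicator in _HBA1C_RESTRICTED:
        mask &= df["knows_hba1c"] == "yes"
    if indicator in _PHASE_2017_RESTRICTED:
        mask &= df["recruitment_phase"] == "2017"
    sub = CohortTable(df.loc[mask].reset_index(drop=True), dict(cohort.provenance))
    return sub, lab[mask.to_numpy()]


def _margins_rows(cohort, labels, indicator, family, adjust):
    sub, lab = _restrict(cohort, labels, indicator)
    fitter = fit_logistic if family == "logistic" else fit_linear
    try:
        fit = fitter(indicator, lab, adjust, sub)
        m = predictive_margins(fit)
        t = m.table.copy()
        t.insert(0, "indicator", indicator)
        t["degenerate"] = False
        return t
    except (ValueError, RuntimeError):
        levels = sorted(pd.unique(labels))
        return pd.DataFrame(
            [{"indicator": indicator, "profile": g, "estimate": np.nan, "se": np.nan,
              "ci_low": np.nan, "ci_high": np.nan, "n_used": 0, "degenerate": True}
             for g in levels]
        )


def compare_profiles(
    cohort: CohortTable,
    labels: Sequence,
    mode: str = "adjusted",
    processes: Optional[Sequence[str]] = None,
    outcomes: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Build the three report tables for a labelled cohort.

    Returns ``processes`` (per-profile probability of each process indicator
    and composite; logistic margins), ``outcomes`` (per-profile mean of each
    continuous outcome, linear margins, plus the binary BP-control indicator
    via logistic margins) and ``table1`` (bivariate tests of participant
    characteristics across profiles). HbA1c-based rows are restricted to
    participants who know what HbA1c is; self-efficacy to the 2017 phase.
    Indicators without variation are emitted flagged degenerate.
    """
    if mode not in ("crude", "adjusted"):
        raise ValueError("mode must be 'crude' or 'adjusted'")
    labels = np.asarray(list(labels))
    if len(labels) != len(cohort):
        raise ValueError("labels do not align with cohort")
    adjust = AdjustmentSet.default() if mode == "adjusted" else AdjustmentSet.crude()
    cohort = add_composites(cohort)

    proc_list = list(processes) if processes is not None else list(PROCESS_COLUMNS + COMPOSITE_COLUMNS)
    out_list = list(outcomes) if outcomes is not None else list(CONTINUOUS_OUTCOMES) + ["bp_below_140_90"]

    proc_tables = [
        _margins_rows(cohort, labels, ind, "logistic", adjust) for ind in proc_list
    ]
    out_tables = [
        _margins_rows(
            cohort, labels, ind,
            "logistic" if ind == "bp_below_140_90" else "linear", adjust,
        )
        for ind in out_list
    ]

    t1_rows = []
    df = cohort.df
    for var in _TABLE1_CONTINUOUS:
        try:
            r = kruskal_wallis(df[var], labels)
            t1_rows.append({"variable": var, "test": "kruskal_wallis",
                            "statistic": r.statistic, "df": r.df,
                            "p_value": r.p_value, "n_used": r.n_used})
        except ValueError:
            t1_rows.append({"variable": var, "test": "kruskal_wallis",
                            "statistic": np.nan, "df": 0, "p_value": np.nan, "n_used": 0})
    for var in CATEGORICAL_LEVELS:
        if var in ("recruitment_phase",) or var not in df.columns:
            continue
        sub = df[var]
        ok = sub.notna()
        if not ok.any():
            continue
        tab = pd.crosstab(sub[ok], pd.Series(labels, index=df.index)[ok])
        tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
        try:
            r = pearson_chi_square(tab.to_numpy())
            t1_rows.append({"variable": var, "test": "chi_square",
                            "statistic": r.statistic, "df": r.df,
                            "p_value": r.p_value, "n_used": r.n_used})
        except ValueError:
            t1_rows.append({"variable": var, "test": "chi_square",
                            "statistic": np.nan, "df": 0, "p_value": np.nan, "n_used": 0})

    empty = pd.DataFrame(
        columns=["indicator", "profile", "estimate", "se", "ci_low", "ci_high",
                 "n_used", "degenerate"]
    )
    return {
        "processes": pd.concat(proc_tables, ignore_index=True) if proc_tables else empty,
        "outcomes": pd.concat(out_tables, ignore_index=True) if out_tables else empty,
        "table1": pd.DataFrame(t1_rows),
    }
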