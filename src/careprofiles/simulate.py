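"""Synthetic cohort generator.

Emulates the data-generating structure the downstream analysis assumes:
each participant belongs to a latent ambulatory-care-use profile; true
annual visit counts per provider are Poisson with profile-specific rates and
are then *binned* to the questionnaire's four ordinal levels (never / once /
2-3 / 4+); covariates, process-of-care indicators and outcome scores are
drawn from profile-conditional models; and a configurable fraction of
records receives missing visit answers completely at random, which is what
triggers the complete-case exclusion downstream.

The bin-then-model mismatch is deliberate: the generator simulates true
counts while the clustering model treats the ordinal pseudo-counts as
Poisson, mirroring how the questionnaire actually measures utilization and
keeping recovery tests honest.

Ground-truth profile labels live only in :class:`SimulatedCohort`; they are
never written into the cohort CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .schema import (
    PROCESS_COLUMNS,
    VISIT_COLUMNS,
    VisitLevel,
)

__all__ = [
    "GeneratorConfig",
    "SimulatedCohort",
    "bin_visit_count",
    "default_config",
    "simulate_cohort",
    "expected_coded_mean",
    "config_to_dict",
    "config_from_dict",
]

PROFILE_NAMES = ("GP & podiatrist", "GP only", "High users", "Diabetologist first")


def bin_visit_count(count: int) -> VisitLevel:
    """Bin an annual visit count to the questionnaire's ordinal level:
    0 → never, 1 → once, 2-3 → 2-3 times, ≥4 → 4 times and more."""
    if count < 0:
        raise ValueError(f"visit count must be nonnegative, got {count}")
    if count == 0:
        return VisitLevel.NEVER
    if count == 1:
        return VisitLevel.ONCE
    if count <= 3:
        return VisitLevel.TWO_THREE
    return VisitLevel.FOUR_PLUS


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    ``pi`` are the K mixing proportions; ``lam`` the K×6 Poisson visit rates
    (visits/year, provider order GP, diabetologist, diabetes nurse,
    dietitian, podiatrist, emergency). ``covariate_models`` holds one entry
    per covariate: ``{"kind": "normal", "mean": [K], "sd": [K], ...}``,
    ``{"kind": "categorical", "levels": [...], "probs": K×L}`` or
    ``{"kind": "count", "mean": [K], "max": int}``. ``process_probs`` is K×8
    over the eight process indicators; ``outcome_models`` per outcome either
    a truncated-normal ``{"mean": [K], "sd": [K], "lo":, "hi":}`` or a
    Bernoulli ``{"probs": [K]}``. ``missing_visits_rate`` is the probability
    a record has at least one missing visit answer (MCAR).
    """

    K: int
    pi: np.ndarray
    lam: np.ndarray
    covariate_models: dict[str, dict[str, Any]]
    process_probs: np.ndarray
    outcome_models: dict[str, dict[str, Any]]
    missing_visits_rate: float
    seed: int

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.process_probs = np.asarray(self.process_probs, dtype=float)

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.pi.shape != (self.K,):
            raise ValueError(f"pi must have shape ({self.K},)")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi entries must be nonnegative and sum to 1 within 1e-12")
        if self.lam.shape != (self.K, 6):
            raise ValueError(f"lam must have shape ({self.K}, 6)")
        if np.any(self.lam < 0):
            raise ValueError("lam entries must be nonnegative")
        if self.process_probs.shape != (self.K, len(PROCESS_COLUMNS)):
            raise ValueError(
                f"process_probs must have shape ({self.K}, {len(PROCESS_COLUMNS)})"
            )
        if np.any((self.process_probs < 0) | (self.process_probs > 1)):
            raise ValueError("process_probs entries must lie in [0, 1]")
        if not (0.0 <= self.missing_visits_rate < 1.0):
            raise ValueError("missing_visits_rate must lie in [0, 1)")


@dataclass
class SimulatedCohort:
    """A generated cohort plus its ground truth (labels 1..K)."""

    cohort: CohortTable
    true_labels: np.ndarray
    true_config: GeneratorConfig

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.cohort.df["id"], "true_profile": self.true_labels}
        )


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default four-profile configuration.

    Mixing proportions equal the observed profile shares (86, 195, 96,
    173)/550; visit-rate rows are shaped so the four profiles read, in
    order: GP-dominant with concomitant podiatry, almost exclusively GP,
    high use of all services, and diabetologist-dominant with low GP use.
    Covariate, process and outcome parameters are qualitative transcriptions
    of the published profile descriptions; they are configurable defaults,
    not estimates.
    """
    pi = np.array([86, 195, 96, 173], dtype=float) / 550.0
    # provider order: gp, diabetologist, diabetes_nurse, dietitian, podiatrist, emergency
    lam = np.array(
        [
            [4.0, 1.2, 0.15, 0.3, 3.5, 0.4],   # GP & podiatrist
            [3.2, 0.1, 0.04, 0.1, 0.2, 0.3],   # GP only
            [4.5, 3.5, 1.5, 1.5, 2.5, 1.2],    # High users
            [1.2, 3.8, 0.4, 0.5, 0.5, 0.4],    # Diabetologist first
        ]
    )
    cat = lambda levels, probs: {"kind": "categorical", "levels": levels, "probs": probs}
    covariate_models = {
        "age": {"kind": "normal", "mean": [69.6, 65.8, 60.7, 55.1],
                "sd": [11.3, 10.3, 13.6, 14.4], "lo": 18, "hi": 95, "round": 0},
        "sex": cat(["female", "male"],
                   [[0.488, 0.512], [0.318, 0.682], [0.510, 0.490], [0.445, 0.555]]),
        "living_arrangement": cat(["alone", "with_others"],
                                  [[0.302, 0.698], [0.231, 0.769], [0.404, 0.596], [0.277, 0.723]]),
        "residential_location": cat(["urban", "intermediary", "rural"],
                                    [[0.659, 0.235, 0.106], [0.624, 0.201, 0.175],
                                     [0.563, 0.260, 0.177], [0.721, 0.163, 0.116]]),
        "education": cat(["primary", "secondary", "tertiary"],
                         [[0.129, 0.624, 0.247], [0.155, 0.562, 0.283],
                          [0.184, 0.552, 0.264], [0.154, 0.462, 0.385]]),
        "income_quartile": cat(["q1", "q2", "q3", "q4"],
                               [[0.286, 0.260, 0.312, 0.143], [0.230, 0.315, 0.326, 0.129],
                                [0.295, 0.295, 0.308, 0.103], [0.159, 0.291, 0.311, 0.238]]),
        "insurance_model": cat(["standard", "alternative"],
                               [[0.741, 0.259], [0.691, 0.309], [0.774, 0.226], [0.720, 0.280]]),
        "subsidies": cat(["yes", "no"],
                         [[0.190, 0.810], [0.168, 0.832], [0.275, 0.725], [0.202, 0.798]]),
        "diabetes_type": cat(["type1", "type2", "other_unknown"],
                             [[0.081, 0.802, 0.116], [0.026, 0.744, 0.231],
                              [0.188, 0.760, 0.052], [0.266, 0.624, 0.110]]),
        "diabetes_duration": cat(["1-10y", ">10y"],
                                 [[0.388, 0.612], [0.630, 0.370], [0.490, 0.510], [0.384, 0.616]]),
        "injectable_medication": cat(["yes", "no"],
                                     [[0.635, 0.365], [0.226, 0.774], [0.750, 0.250], [0.715, 0.285]]),
        "n_complications": {"kind": "count", "mean": [0.7, 0.4, 1.0, 0.6], "max": 9},
        "self_monitoring": cat(["yes", "no"],
                               [[0.894, 0.106], [0.649, 0.351], [0.957, 0.043], [0.919, 0.081]]),
        "knows_hba1c": cat(["yes", "no"],
                           [[0.782, 0.218], [0.641, 0.359], [0.897, 0.103], [0.865, 0.135]]),
        "education_courses": cat(["yes", "no"],
                                 [[0.388, 0.612], [0.170, 0.830], [0.462, 0.538], [0.444, 0.556]]),
        "association_member": cat(["yes", "no"],
                                  [[0.212, 0.788], [0.036, 0.964], [0.237, 0.763], [0.173, 0.827]]),
        "self_rated_health": cat(["excellent", "very_good", "good", "fair", "poor"],
                                 [[0.024, 0.121, 0.602, 0.217, 0.036],
                                  [0.026, 0.142, 0.642, 0.168, 0.021],
                                  [0.011, 0.096, 0.543, 0.255, 0.096],
                                  [0.023, 0.151, 0.628, 0.163, 0.035]]),
        "n_comorbidities": {"kind": "count", "mean": [2.1, 1.8, 2.0, 1.4], "max": 11},
        "bmi_category": cat(["underweight", "normal", "overweight", "obese"],
                            [[0.000, 0.193, 0.313, 0.494], [0.005, 0.151, 0.398, 0.446],
                             [0.022, 0.178, 0.311, 0.489], [0.006, 0.227, 0.362, 0.405]]),
        "smoking": cat(["never_former", "current"],
                       [[0.869, 0.131], [0.813, 0.187], [0.839, 0.161], [0.791, 0.209]]),
        "physical_activity": cat(["active", "partially_active", "inactive"],
                                 [[0.476, 0.207, 0.317], [0.505, 0.191, 0.304],
                                  [0.645, 0.118, 0.237], [0.544, 0.213, 0.243]]),
        "depression_screen": cat(["yes", "no"],
                                 [[0.337, 0.663], [0.301, 0.699], [0.453, 0.547], [0.345, 0.655]]),
        "hospitalizations": cat(["none", "once", "more_than_once"],
                                [[0.767, 0.128, 0.105], [0.794, 0.165, 0.041],
                                 [0.645, 0.183, 0.172], [0.794, 0.147, 0.059]]),
        "forgone_care": cat(["yes", "no"],
                            [[0.209, 0.791], [0.103, 0.897], [0.167, 0.833], [0.220, 0.780]]),
        "recruitment_phase": cat(["2011", "2017"],
                                 [[0.5, 0.5]] * 4),
    }
    # process order: eye_exam_24m, foot_exam, microalbuminuria, cholesterol,
    # flu_shot, hba1c_twice, bp_twice, activity_diet_advice
    process_probs = np.array(
        [
            [0.85, 0.78, 0.75, 0.96, 0.58, 0.85, 0.88, 0.55],
            [0.67, 0.38, 0.70, 0.96, 0.52, 0.81, 0.80, 0.45],
            [0.90, 0.79, 0.80, 0.97, 0.60, 0.91, 0.91, 0.70],
            [0.86, 0.75, 0.76, 0.97, 0.55, 0.89, 0.87, 0.55],
        ]
    )
    outcome_models = {
        "sf12_pcs": {"mean": [41.0, 45.0, 39.0, 46.0], "sd": [10.0] * 4, "lo": 0, "hi": 100},
        "sf12_mcs": {"mean": [47.0, 50.0, 45.0, 49.0], "sd": [10.0] * 4, "lo": 0, "hi": 100},
        "addqol": {"mean": [-1.8, -1.2, -2.2, -1.5], "sd": [1.6] * 4, "lo": -9, "hi": 3},
        "pacic": {"mean": [2.9, 2.4, 3.3, 2.8], "sd": [0.9] * 4, "lo": 1, "hi": 5},
        "self_efficacy": {"mean": [6.9, 7.3, 6.7, 7.2], "sd": [1.8] * 4, "lo": 1, "hi": 10},
        "hba1c_value": {"mean": [7.0, 6.9, 7.4, 7.3], "sd": [1.1] * 4, "lo": 4, "hi": 15},
        "bp_below_140_90": {"probs": [0.573, 0.65, 0.67, 0.764]},
    }
    cfg = GeneratorConfig(
        K=4,
        pi=pi,
        lam=lam,
        covariate_models=covariate_models,
        process_probs=process_probs,
        outcome_models=outcome_models,
        missing_visits_rate=483 / 1033,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _draw_covariate(rng: np.random.Generator, model: dict, z: np.ndarray) -> pd.Series:
    n = len(z)
    kind = model["kind"]
    if kind == "normal":
        mean = np.asarray(model["mean"], float)[z]
        sd = np.asarray(model["sd"], float)[z]
        x = np.clip(rng.normal(mean, sd), model.get("lo", -np.inf), model.get("hi", np.inf))
        nd = model.get("round")
        if nd is not None:
            x = np.round(x, nd)
            if nd == 0:
                return pd.Series(x.astype(int))
        return pd.Series(x)
    if kind == "categorical":
        probs = np.asarray(model["probs"], float)
        probs = probs / probs.sum(axis=1, keepdims=True)
        levels = np.asarray(model["levels"], object)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)[z]
        idx = (u[:, None] > cum).sum(axis=1)
        return pd.Series(levels[idx])
    if kind == "count":
        mean = np.asarray(model["mean"], float)[z]
        return pd.Series(np.minimum(rng.poisson(mean), model["max"]).astype(int))
    raise ValueError(f"unknown covariate model kind {kind!r}")


def simulate_cohort(config: GeneratorConfig, n: int) -> SimulatedCohort:
    """Draw a cohort of n participants from the generative model.

    One explicitly seeded random stream drives all draws, so identical
    (config, n) reproduces the identical cohort byte-for-byte.
    """
    config.validate()
    if n < config.K:
        raise ValueError(f"n={n} must be at least K={config.K}")
    rng = np.random.default_rng(config.seed)
    z = rng.choice(config.K, size=n, p=config.pi)  # 0-based internally

    df = pd.DataFrame({"id": [f"P{i + 1:05d}" for i in range(n)]})

    counts = rng.poisson(config.lam[z])  # n×6 true annual counts
    for j, col in enumerate(VISIT_COLUMNS):
        toks = [bin_visit_count(int(c)).token for c in counts[:, j]]
        df[col] = pd.Categorical(
            toks, categories=[lv.token for lv in VisitLevel], ordered=True
        )

    for cov, model in config.covariate_models.items():
        df[cov] = _draw_covariate(rng, model, z)

    proc = (rng.random((n, len(PROCESS_COLUMNS))) < config.process_probs[z]).astype(int)
    for j, col in enumerate(PROCESS_COLUMNS):
        df[col] = pd.array(proc[:, j], dtype="Int64")

    for out, model in config.outcome_models.items():
        if "probs" in model:
            p = np.asarray(model["probs"], float)[z]
            df[out] = pd.array((rng.random(n) < p).astype(int), dtype="Int64")
        else:
            mean = np.asarray(model["mean"], float)[z]
            sd = np.asarray(model["sd"], float)[z]
            x = np.clip(rng.normal(mean, sd), model["lo"], model["hi"])
            df[out] = np.round(x, 1)

    # Structural missingness: six-process indicator and HbA1c value are only
    # defined for participants who know what HbA1c is; self-efficacy was
    # collected in the 2017 phase only.
    if "knows_hba1c" in df.columns:
        unknown = df["knows_hba1c"] != "yes"
        df.loc[unknown, "hba1c_twice"] = pd.NA
        df.loc[unknown, "hba1c_value"] = np.nan
    if "recruitment_phase" in df.columns and "self_efficacy" in df.columns:
        df.loc[df["recruitment_phase"] != "2017", "self_efficacy"] = np.nan

    # MCAR missingness on the visit variables only.
    if config.missing_visits_rate > 0:
        hit = rng.random(n) < config.missing_visits_rate
        n_missing = 1 + rng.binomial(5, 0.25, size=n)
        for i in np.flatnonzero(hit):
            cols = rng.choice(6, size=n_missing[i], replace=False)
            for j in cols:
                df.iloc[i, df.columns.get_loc(VISIT_COLUMNS[j])] = np.nan

    cohort = CohortTable(df, provenance={"generator_seed": config.seed, "n": n})
    return SimulatedCohort(cohort, true_labels=z + 1, true_config=config)


def expected_coded_mean(lam, scheme: str = "primary") -> np.ndarray:
    """Expected pseudo-count of a binned Poisson(λ) visit count.

    The questionnaire bins the true annual count into four ordinal levels
    which the coding scheme then maps back to pseudo-counts, so the mean
    observed pseudo-count is not λ itself but

        m(λ) = c₁·P(Y=1) + c₂₃·P(Y∈{2,3}) + c₄·P(Y≥4),  Y ~ Poisson(λ),

    with (c₁, c₂₃, c₄) the scheme's codes for once / 2-3 / 4+. This is the
    quantity the mixture's rate estimates actually target, and the honest
    reference for parameter-recovery checks.
    """
    from scipy.stats import poisson

    from .cohort import get_scheme

    lam = np.asarray(lam, dtype=float)
    s = get_scheme(scheme).mapping
    p = [poisson.pmf(k, lam) for k in range(4)]
    return (
        s[VisitLevel.ONCE] * p[1]
        + s[VisitLevel.TWO_THREE] * (p[2] + p[3])
        + s[VisitLevel.FOUR_PLUS] * (1.0 - p[0] - p[1] - p[2] - p[3])
    )


# ---------------------------------------------------------------------------
# YAML-friendly (de)serialization, mirrored field-for-field
# ---------------------------------------------------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "K": config.K,
        "pi": config.pi.tolist(),
        "lam": config.lam.tolist(),
        "covariate_models": config.covariate_models,
        "process_probs": config.process_probs.tolist(),
        "outcome_models": config.outcome_models,
        "missing_visits_rate": config.missing_visits_rate,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    cfg = GeneratorConfig(
        K=int(d["K"]),
        pi=np.asarray(d["pi"], float),
        lam=np.asarray(d["lam"], float),
        covariate_models=d["covariate_models"],
        process_probs=np.asarray(d["process_probs"], float),
        outcome_models=d["outcome_models"],
        missing_visits_rate=float(d["missing_visits_rate"]),
        seed=int(d["seed"]),
    )
    cfg.validate()
    return cfg
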