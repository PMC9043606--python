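"""Finite mixture of independent Poisson distributions, fitted by EM.

The model for the 6-vector of pseudo-counts y_i is

    P(y_i) = Σ_k π_k Π_j Poisson(y_ij; λ_kj),

i.e. the six providers are independent given the latent profile k. EM
alternates posterior responsibilities (E) with closed-form weighted MLE
updates (M): π_k ← mean responsibility, λ_kj ← responsibility-weighted
column mean. Multiple random restarts guard against local maxima; the best
final log-likelihood wins. Components are reported in a canonical order —
descending total expected visits Σ_j λ_kj — so the heaviest-use profile is
always first regardless of initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cohort import CohortTable, encode_visits, get_scheme
from .schema import PROVIDERS, VISIT_COLUMNS

__all__ = [
    "MixtureParams",
    "FitOptions",
    "FitResult",
    "log_likelihood",
    "fit_em",
    "bic",
    "map_assign",
    "profile_mean_visits",
    "n_mixture_params",
]


@dataclass
class MixtureParams:
    """Mixing proportions π (K,) and Poisson rate matrix λ (K×6)."""

    K: int
    pi: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        if self.pi.shape != (self.K,):
            raise ValueError(f"pi must have shape ({self.K},)")
        if self.lam.shape[0] != self.K:
            raise ValueError(f"lam must have {self.K} rows")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be nonnegative and sum to 1 within 1e-10")
        if np.any(self.lam < 0):
            raise ValueError("lam must be nonnegative")


@dataclass
class FitOptions:
    """EM settings. The seed is required for reproducible restarts."""

    n_starts: int = 20
    max_iter: int = 1000
    rel_tol: float = 1e-8
    seed: int = 0
    rate_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_starts < 1 or self.max_iter < 1 or self.rel_tol <= 0:
            raise ValueError("n_starts >= 1, max_iter >= 1 and rel_tol > 0 required")


@dataclass
class FitResult:
    params: MixtureParams
    loglik: float
    loglik_trace: np.ndarray
    responsibilities: np.ndarray
    converged: bool
    n_params: int
    bic: float
    best_start: int
    n_obs: int
    degenerate: bool = False


def n_mixture_params(K: int, n_features: int = 6) -> int:
    """Free parameters: K−1 mixing proportions plus K·6 rates."""
    return (K - 1) + n_features * K


def _check_count_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D count matrix")
    if np.any(data < 0) or not np.all(np.equal(np.mod(data, 1), 0)):
        raise ValueError(
            "data must contain nonnegative integers; use the primary or "
            "sensitivity coding scheme (plot_means is for descriptive means only)"
        )
    return data.astype(np.int64)


def _component_logpmf(data: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """n×K matrix of log Π_j Poisson(y_ij; λ_kj)."""
    lam = np.maximum(lam, 1e-300)  # guard log(0); λ=0 means support {0} only
    const = gammaln(data + 1).sum(axis=1)
    return data @ np.log(lam).T - lam.sum(axis=1) - const[:, None]


def log_likelihood(data: np.ndarray, params: MixtureParams) -> float:
    """Mixture log-likelihood, computed in log space (stable over components)."""
    data = _check_count_data(data)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    lp = _component_logpmf(data, params.lam) + logpi
    return float(logsumexp(lp, axis=1).sum())


def _canonical_order(lam: np.ndarray) -> np.ndarray:
    """Component order: descending total expected visits (stable on ties)."""
    totals = lam.sum(axis=1)
    return np.argsort(-totals, kind="stable")


def _em_single(
    data: np.ndarray, K: int, opts: FitOptions, rng: np.random.Generator
) -> tuple[MixtureParams, float, np.ndarray, np.ndarray, bool, bool]:
    n = data.shape[0]
    resp = rng.dirichlet(np.ones(K), size=n)
    trace: list[float] = []
    converged = False
    degenerate = False
    pi = resp.mean(axis=0)
    lam = np.maximum((resp.T @ data) / resp.sum(axis=0)[:, None], opts.rate_floor)
    out_pi, out_lam, out_resp, ll = pi, lam, resp, -np.inf
    for _ in range(opts.max_iter):
        with np.errstate(divide="ignore"):
            lp = _component_logpmf(data, lam) + np.log(np.maximum(pi, 1e-300))
        norm = logsumexp(lp, axis=1)
        prev_ll, ll = ll, float(norm.sum())
        resp = np.exp(lp - norm[:, None])
        trace.append(ll)
        out_pi, out_lam, out_resp = pi, lam, resp  # params that produced ll
        if np.isfinite(prev_ll):
            denom = abs(prev_ll) if prev_ll != 0 else 1.0
            if abs(ll - prev_ll) / denom < opts.rel_tol:
                converged = True
                break
        pi = resp.mean(axis=0)
        if np.any(pi < 1.0 / (10.0 * n)):
            degenerate = True
            break
        lam = np.maximum((resp.T @ data) / resp.sum(axis=0)[:, None], opts.rate_floor)
    params = MixtureParams(K, out_pi / out_pi.sum(), out_lam)
    return params, trace[-1], np.array(trace), out_resp, converged, degenerate


def fit_em(
    data: np.ndarray, K: int, opts: Optional[FitOptions] = None
) -> FitResult:
    """Fit a K-component product-Poisson mixture by EM with random restarts.

    Responsibilities are initialized from a flat Dirichlet per record. A
    start whose smallest mixing proportion collapses below 1/(10n) is
    restarted with a fresh draw (up to 3 extra attempts) before being
    accepted as degenerate. Returns the best start by final log-likelihood.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    data = _check_count_data(data)
    n = data.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} observations, got {n}")
    opts = opts or FitOptions()
    all_identical = bool(np.all(data == data[0]))

    ss = np.random.SeedSequence(opts.seed)
    best = None
    for start, child in enumerate(ss.spawn(opts.n_starts)):
        rng = np.random.default_rng(child)
        attempt = 0
        while True:
            params, ll, trace, resp, conv, degen = _em_single(data, K, opts, rng)
            if not degen or attempt >= 3:
                break
            attempt += 1
        if best is None or ll > best[1]:
            best = (params, ll, trace, resp, conv, degen, start)

    params, ll, trace, resp, conv, degen, start = best
    order = _canonical_order(params.lam)
    params = MixtureParams(K, params.pi[order], params.lam[order])
    resp = resp[:, order]
    p = n_mixture_params(K, data.shape[1])
    return FitResult(
        params=params,
        loglik=ll,
        loglik_trace=trace,
        responsibilities=resp,
        converged=conv,
        n_params=p,
        bic=-2.0 * ll + p * np.log(n),
        best_start=start,
        n_obs=n,
        degenerate=degen or (all_identical and K > 1),
    )


def bic(fit: FitResult, n: Optional[int] = None) -> float:
    """BIC = −2 log L + p ln n with p = (K−1) + 6K; lower is better."""
    n = fit.n_obs if n is None else n
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * fit.loglik + fit.n_params * np.log(n)


def map_assign(fit: FitResult) -> np.ndarray:
    """Hard profile labels (1..K) by maximum posterior responsibility.

    Ties break toward the lower canonical label index, i.e. the profile
    with more total expected visits.
    """
    return fit.responsibilities.argmax(axis=1) + 1


def profile_mean_visits(
    cohort: CohortTable, labels: Sequence[int], K: Optional[int] = None
) -> pd.DataFrame:
    """Mean visits per provider and profile on the plot-means recoding
    (never→0, once→1, 2-3→2.5, 4+→4); the tabular analog of the mean-visit
    profile plot. Empty profiles get NaN rows.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels do not align with cohort")
    K = K or int(labels.max())
    mat = encode_visits(cohort, get_scheme("plot_means"))
    rows = []
    for k in range(1, K + 1):
        mask = labels == k
        rows.append(mat[mask].mean(axis=0) if mask.any() else np.full(6, np.nan))
    return pd.DataFrame(rows, index=pd.Index(range(1, K + 1), name="profile"),
                        columns=list(PROVIDERS))
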