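"""Choosing the number of profiles: BIC sweep over K and the clustergram.

The sweep fits K = 1..k_max mixtures with per-K seeds derived
deterministically from one master seed, tabulates log-likelihood and BIC,
and selects the converged K with minimum BIC (ties toward smaller K). The
clustergram records, for each K, the size and mean total recoded visits of
every cluster, and for each adjacent pair (K, K+1) the number of
observations flowing from each cluster to each successor — the data behind
the reassignment diagnostic used alongside BIC. Selection here is by BIC
alone; the clustergram is emitted for human inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .mixture import FitOptions, FitResult, fit_em, map_assign

__all__ = ["KSweepResult", "ClustergramData", "sweep_k", "build_clustergram",
           "plot_clustergram", "derive_k_seed"]

#: pseudo-count → plot-means score; covers the primary (2) and sensitivity
#: (3) codings of the middle ordinal category, both scored at 2.5 for plots.
_PLOT_SCORE = {0: 0.0, 1: 1.0, 2: 2.5, 3: 2.5, 4: 4.0}


def derive_k_seed(master_seed: int, k: int) -> int:
    """Deterministic per-K seed so the sweep is reproducible as a unit."""
    return int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class KSweepResult:
    table: pd.DataFrame  # columns: K, loglik, n_params, bic, converged
    selected_K: int
    fits: dict[int, FitResult]


@dataclass
class ClustergramData:
    """Per-K cluster summaries and between-K observation flows."""

    n: int
    levels: dict[int, pd.DataFrame]  # K -> (cluster, size, mean_total_visits)
    flows: dict[int, pd.DataFrame]   # K -> edges (from_cluster, to_cluster, n) into K+1

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "levels": {str(k): df.to_dict("records") for k, df in self.levels.items()},
            "flows": {str(k): df.to_dict("records") for k, df in self.flows.items()},
        }


def _fit_range(data: np.ndarray, k_max: int, opts: FitOptions) -> dict[int, FitResult]:
    return {
        k: fit_em(data, k, replace(opts, seed=derive_k_seed(opts.seed, k)))
        for k in range(1, k_max + 1)
    }


def sweep_k(data: np.ndarray, k_max: int, opts: Optional[FitOptions] = None) -> KSweepResult:
    """Fit K = 1..k_max and select the minimum-BIC converged model."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    opts = opts or FitOptions()
    fits = _fit_range(data, k_max, opts)
    rows = [
        {
            "K": k,
            "loglik": f.loglik,
            "n_params": f.n_params,
            "bic": f.bic,
            "converged": f.converged,
        }
        for k, f in fits.items()
    ]
    table = pd.DataFrame(rows)
    usable = table[table["converged"]]
    if usable.empty:
        raise RuntimeError("no K converged; increase max_iter or n_starts")
    # idxmin on an ascending-K table breaks BIC ties toward smaller K
    selected = int(usable.loc[usable["bic"].idxmin(), "K"])
    return KSweepResult(table=table, selected_K=selected, fits=fits)


def build_clustergram(
    data: np.ndarray, k_max: int, opts: Optional[FitOptions] = None
) -> ClustergramData:
    """Cluster summaries per K and observation flows between adjacent K.

    The summary value of a cluster is the mean, over its members, of the
    total visits across the six providers on the plot-means recoding.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2 for a clustergram")
    opts = opts or FitOptions()
    fits = _fit_range(data, k_max, opts)
    totals = np.vectorize(_PLOT_SCORE.get)(np.asarray(data)).sum(axis=1)
    labels = {k: map_assign(f) for k, f in fits.items()}
    levels = {}
    for k, lab in labels.items():
        rows = []
        for c in range(1, k + 1):
            mask = lab == c
            rows.append(
                {
                    "cluster": c,
                    "size": int(mask.sum()),
                    "mean_total_visits": float(totals[mask].mean()) if mask.any() else float("nan"),
                }
            )
        levels[k] = pd.DataFrame(rows)
    flows = {}
    for k in range(1, k_max):
        a, b = labels[k], labels[k + 1]
        edges = (
            pd.DataFrame({"from_cluster": a, "to_cluster": b})
            .value_counts()
            .rename("n")
            .reset_index()
            .sort_values(["from_cluster", "to_cluster"])
            .reset_index(drop=True)
        )
        flows[k] = edges
    return ClustergramData(n=int(np.asarray(data).shape[0]), levels=levels, flows=flows)


def plot_clustergram(cg: ClustergramData, ax=None):
    """Render the clustergram: cluster summary values by K, with line widths
    proportional to the number of observations flowing between clusters."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    pos = {
        (k, row["cluster"]): (k, row["mean_total_visits"])
        for k, df in cg.levels.items()
        for _, row in df.iterrows()
    }
    for k, edges in cg.flows.items():
        for _, e in edges.iterrows():
            x0, y0 = pos[(k, e["from_cluster"])]
            x1, y1 = pos[(k + 1, e["to_cluster"])]
            ax.plot([x0, x1], [y0, y1], color="steelblue", alpha=0.6,
                    linewidth=0.5 + 8.0 * e["n"] / cg.n, solid_capstyle="round")
    for (k, _), (x, y) in pos.items():
        ax.plot([x], [y], "o", color="black", markersize=3)
    ax.set_xlabel("number of clusters K")
    ax.set_ylabel("mean total visits (plot recoding)")
    ax.set_xticks(sorted(cg.levels))
    return ax
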