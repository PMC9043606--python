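import numpy as np
import pytest

import careprofiles as cp


@pytest.fixture(scope="session")
def clean_cohort():
    """Simulated cohort without visit missingness (complete clustering data)."""
    cfg = cp.default_config(seed=11)
    cfg.missing_visits_rate = 0.0
    return cp.simulate_cohort(cfg, 400)


@pytest.fixture(scope="session")
def messy_cohort():
    """Simulated cohort with the default missing-visit rate."""
    cfg = cp.default_config(seed=12)
    return cp.simulate_cohort(cfg, 500)


@pytest.fixture(scope="session")
def labelled_cohort():
    """Complete-case cohort, its pseudo-count matrix and fitted MAP labels."""
    cfg = cp.default_config(seed=13)
    sim = cp.simulate_cohort(cfg, 600)
    kept, _ = cp.filter_clustering_complete(sim.cohort)
    data = cp.encode_visits(kept, "primary")
    fit = cp.fit_em(data, 4, cp.FitOptions(n_starts=10, seed=13))
    return kept, data, fit, cp.map_assign(fit)


def match_to_reference(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Permutation of estimated mixture components minimizing the summed
    squared distance of rate rows to a reference matrix (label switching)."""
    from scipy.optimize import linear_sum_assignment

    cost = ((est[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[cols] = rows
    return perm
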