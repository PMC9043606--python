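"""End-to-end orchestration: simulate/read → complete-case filter → cluster
→ K selection → descriptive tables → profile comparison, with one master
seed and a reproducibility manifest.

Every stage writes a versioned, stable filename into the output directory;
the manifest records the package version, a hash of the configuration, the
seeds used, per-stage record counts and a SHA-256 digest of every output
file, so a rerun with the same configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    crosstab_percent,
    encode_visits,
    filter_clustering_complete,
    get_scheme,
    read_cohort,
    write_cohort,
)
from .compare import compare_profiles
from .mixture import FitOptions, fit_em, map_assign, profile_mean_visits
from .selection import build_clustergram, sweep_k
from .simulate import config_from_dict, default_config, simulate_cohort

logger = logging.getLogger("careprofiles")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Exactly one of ``input`` (a cohort CSV path) or ``generator`` (a
    synthetic-cohort configuration dict, or ``"default"``) must be given.
    ``k`` fixes the number of profiles; otherwise the BIC sweep up to
    ``k_max`` selects it.
    """

    input: Optional[str] = None
    generator: Optional[Any] = None
    n: int = 550
    coding: str = "primary"
    k: Optional[int] = None
    k_max: int = 6
    n_starts: int = 20
    max_iter: int = 1000
    rel_tol: float = 1e-8
    mode: str = "adjusted"
    out_dir: str = "careprofiles_run"
    seed: int = 0

    def validate(self) -> None:
        if (self.input is None) == (self.generator is None):
            raise ValueError("exactly one of 'input' and 'generator' must be set")
        if self.input is not None and not Path(self.input).exists():
            raise ValueError(f"input file {self.input!r} does not exist")
        if self.coding not in ("primary", "sensitivity"):
            raise ValueError("coding must be 'primary' or 'sensitivity'")
        if self.mode not in ("crude", "adjusted"):
            raise ValueError("mode must be 'crude' or 'adjusted'")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    n_read: int
    n_excluded: int
    n_clustered: int
    selected_k: int
    digests: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing every intermediate artifact.

    Outputs in ``out_dir``: cohort.csv, labels.csv, params.json, sweep.csv,
    clustergram.json, table1.csv, fig1_table.csv, fig2_table.csv,
    fig3_table.csv, manifest.json.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def stage(name):
        logger.info("stage=%s seed=%d", name, config.seed)

    stage("input")
    if config.input is not None:
        cohort = read_cohort(config.input)
    else:
        gen = (
            default_config(seed=config.seed)
            if config.generator == "default"
            else config_from_dict(dict(config.generator))
        )
        cohort = simulate_cohort(gen, config.n).cohort
    n_read = len(cohort)
    cohort_path = out / "cohort.csv"
    write_cohort(cohort, cohort_path)
    outputs.append(cohort_path)

    stage("filter")
    kept, n_excluded = filter_clustering_complete(cohort)
    data = encode_visits(kept, get_scheme(config.coding))

    stage("select-k")
    opts = FitOptions(
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        rel_tol=config.rel_tol,
        seed=config.seed,
    )
    sweep = sweep_k(data, config.k_max, opts)
    sweep_path = out / "sweep.csv"
    sweep.table.to_csv(sweep_path, index=False)
    outputs.append(sweep_path)
    selected_k = config.k if config.k is not None else sweep.selected_K

    stage("cluster")
    fit = sweep.fits.get(selected_k) or fit_em(data, selected_k, opts)
    labels = map_assign(fit)
    labels_path = out / "labels.csv"
    pd.DataFrame({"id": kept.df["id"], "profile": labels}).to_csv(labels_path, index=False)
    outputs.append(labels_path)
    params_path = out / "params.json"
    params_path.write_text(
        json.dumps(
            {
                "K": fit.params.K,
                "pi": fit.params.pi.tolist(),
                "lambda": fit.params.lam.tolist(),
                "loglik": fit.loglik,
                "bic": fit.bic,
                "converged": fit.converged,
                "n_starts": opts.n_starts,
                "seed": opts.seed,
                "coding": config.coding,
            },
            indent=2,
        )
    )
    outputs.append(params_path)

    stage("clustergram")
    cg = build_clustergram(data, config.k_max, opts)
    cg_path = out / "clustergram.json"
    cg_path.write_text(json.dumps(cg.to_dict(), indent=2))
    outputs.append(cg_path)

    stage("describe")
    fig1 = profile_mean_visits(kept, labels, K=selected_k)
    fig1_path = out / "fig1_table.csv"
    fig1.to_csv(fig1_path)
    outputs.append(fig1_path)

    stage("compare")
    tables = compare_profiles(kept, labels, mode=config.mode)
    paths = {"table1": "table1.csv", "processes": "fig2_table.csv", "outcomes": "fig3_table.csv"}
    for key, fname in paths.items():
        p = out / fname
        tables[key].to_csv(p, index=False)
        outputs.append(p)

    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        seed=config.seed,
        n_read=n_read,
        n_excluded=n_excluded,
        n_clustered=len(kept),
        selected_k=selected_k,
        digests={p.name: _sha256(p) for p in outputs},
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    logger.info("stage=done read=%d excluded=%d clustered=%d k=%d",
                n_read, n_excluded, len(kept), selected_k)
    return manifest
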