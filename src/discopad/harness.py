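"""Repetition harness comparing correlation-based Meff estimators against
per-repetition permutation gold standards, with median/MAD/RMSE summaries."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import synthetic
from .assoc import correlation_matrix
from .meff import (
    adjusted_pwer,
    effective_tests_from_pwer,
    grouped_from_matrix,
    meff_from_matrix,
)
from .permutation import permutation_gold
from .types import DataError, GroupPartition

log = logging.getLogger(__name__)

__all__ = ["rmse", "median_mad", "SimulationConfig", "SimulationReport", "run_simulation"]


def rmse(estimates, golds) -> float:
    """Root-mean-squared error of estimates against per-repetition golds."""
    estimates = np.asarray(estimates, dtype=float)
    golds = np.asarray(golds, dtype=float)
    if estimates.shape != golds.shape or estimates.ndim != 1 or estimates.size < 1:
        raise DataError("estimate and gold vectors must have equal length >= 1")
    return float(np.sqrt(np.mean((estimates - golds) ** 2)))


def median_mad(values, scale: float = 1.0):
    """(median, median absolute deviation). Unscaled MAD by default; pass
    scale=1.4826 for the normal-consistent convention."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise DataError("need a non-empty vector")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med))) * scale
    return med, mad


@dataclass
class SimulationConfig:
    """Grid and generator settings for one simulation study.

    generator: "identity" | "block" | "nonlinear" | "template"
    groupings: map label -> GroupPartition (or None for ungrouped)
    """

    generator: str = "identity"
    gen_params: dict = field(default_factory=dict)
    n: int = 100
    M: int = 20
    reps: int = 10
    K: int = 1000
    alpha: float = 0.05
    estimators: tuple = ("nyholt", "liji", "gao", "galwey", "peluso")
    corr_methods: tuple = ("pearson", "distance")
    groupings: dict = field(default_factory=lambda: {"ungrouped": None})
    outcome_kind: str = "continuous"
    test: str = "regression"
    seed: int = 0
    engine: str = "naive"
    mad_scale: float = 1.0
    peluso_lambda: str = "max"

    def __post_init__(self):
        if int(np.floor(self.alpha * self.K)) < 1:
            raise DataError("infeasible config: floor(alpha*K) < 1")
        if self.reps < 1:
            raise DataError("reps must be >= 1")


@dataclass
class SimulationReport:
    """Per-cell Meff estimates over repetitions plus summary statistics."""

    config: SimulationConfig
    gold: np.ndarray
    estimates: dict  # (estimator, corr_method, grouping) -> np.ndarray
    baselines: dict  # (estimator, grouping) -> np.ndarray

    def gold_summary(self):
        return median_mad(self.gold, scale=self.config.mad_scale)

    def cell_summary(self, key):
        est = self.estimates[key] if key in self.estimates else self.baselines[key]
        med, _ = median_mad(est, scale=self.config.mad_scale)
        return med, rmse(est, self.gold)

    def to_dict(self) -> dict:
        med, mad = self.gold_summary()
        out = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if k != "groupings"
            },
            "groupings": list(self.config.groupings),
            "gold": {"values": self.gold.tolist(), "median": med, "mad": mad},
            "cells": {},
        }
        for key, vals in {**self.baselines, **self.estimates}.items():
            m, r = self.cell_summary(key)
            out["cells"]["|".join(key)] = {
                "values": np.asarray(vals).tolist(),
                "median": m,
                "rmse": r,
            }
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_table(self) -> str:
        """Table-style TSV: rows = estimator, columns = corr x grouping,
        cells = "median (RMSE)" rounded to nearest integer."""
        groupings = list(self.config.groupings)
        med, mad = self.gold_summary()
        lines = [f"gold-standard\t{med:.0f} ({mad:.0f})"]
        cols = [
            f"{corr}:{grp}"
            for grp in groupings
            for corr in self.config.corr_methods
        ]
        lines.append("estimator\t" + "\t".join(cols))
        for est in ("bonferroni", "sidak"):
            if (est, "none") in self.baselines:
                m, r = self.cell_summary((est, "none"))
                lines.append(est + "\t" + "\t".join(f"{m:.0f} ({r:.0f})" for _ in cols))
        for est in self.config.estimators:
            cells = []
            for grp in groupings:
                for corr in self.config.corr_methods:
                    m, r = self.cell_summary((est, corr, grp))
                    cells.append(f"{m:.0f} ({r:.0f})")
            lines.append(est + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def _generate(cfg: SimulationConfig, seed: int):
    p = dict(cfg.gen_params)
    if cfg.generator == "identity":
        return synthetic.iid_normal(cfg.M, cfg.n, seed)
    if cfg.generator == "block":
        sizes = p.get("block_sizes") or [p.get("block_size", cfg.M)] * (
            cfg.M // p.get("block_size", cfg.M)
        )
        return synthetic.block_correlated(cfg.M, sizes, p.get("rho", 0.5), cfg.n, seed)
    if cfg.generator == "nonlinear":
        return synthetic.nonlinear_pairs(
            cfg.M // 2, cfg.n, p.get("noise_sd", 0.1), p.get("form", "square"), seed
        )
    if cfg.generator == "template":
        return synthetic.mvn_from_template(p["mean"], p["cov"], cfg.n, seed)
    raise DataError(f"unknown generator: {cfg.generator!r}")


def run_simulation(cfg: SimulationConfig) -> SimulationReport:
    """Run the repetition loop.

    Per repetition: generate features and a null outcome, compute the
    permutation gold standard, then every requested (estimator x
    correlation x grouping) Meff estimate from the same dataset. All
    randomness derives from the master seed via spawned substreams, so the
    report does not depend on execution order or worker count.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rep_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(cfg.reps * 3)]

    gold = np.empty(cfg.reps)
    estimates = {
        (est, corr, grp): np.empty(cfg.reps)
        for est in cfg.estimators
        for corr in cfg.corr_methods
        for grp in cfg.groupings
    }
    baselines = {}
    sidak_meff = effective_tests_from_pwer(
        cfg.alpha, adjusted_pwer(cfg.alpha, cfg.M, "sidak-type").pwer
    )
    baselines[("bonferroni", "none")] = np.full(cfg.reps, float(cfg.M))
    baselines[("sidak", "none")] = np.full(cfg.reps, sidak_meff)

    for rep in range(cfg.reps):
        s_data, s_outcome, s_perm = rep_seeds[3 * rep : 3 * rep + 3]
        X = _generate(cfg, s_data)
        y = synthetic.null_outcome(cfg.n, cfg.outcome_kind, s_outcome)
        g = permutation_gold(
            X, y, alpha=cfg.alpha, K=cfg.K, seed=s_perm, test=cfg.test
        )
        gold[rep] = g.meff0
        for corr in cfg.corr_methods:
            A = correlation_matrix(X, corr, engine=cfg.engine)
            for grp_label, partition in cfg.groupings.items():
                for est in cfg.estimators:
                    kw = dict(peluso_lambda=cfg.peluso_lambda)
                    if partition is None:
                        val = meff_from_matrix(A, est, **kw).value
                    else:
                        val = grouped_from_matrix(A, partition, est, **kw).value
                    estimates[(est, corr, grp_label)][rep] = val
        log.debug("rep %d/%d done (gold=%.1f)", rep + 1, cfg.reps, gold[rep])

    return SimulationReport(config=cfg, gold=gold, estimates=estimates, baselines=baselines)
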