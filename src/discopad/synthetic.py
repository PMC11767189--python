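"""Synthetic feature matrices, outcomes, and groupings for testing.

All generators are pure functions of their parameters and a seed.
"""
from __future__ import annotations

import warnings

import numpy as np

from .psd import is_psd, nearest_psd
from .types import (
    AssociationMatrix,
    DataError,
    FeatureMatrix,
    GroupPartition,
    OutcomeVector,
)

__all__ = [
    "mvn_from_template",
    "block_correlated",
    "nonlinear_pairs",
    "null_outcome",
    "random_partition",
    "iid_normal",
]


def _feature_ids(m: int, prefix: str = "f") -> list:
    return [f"{prefix}{i + 1}" for i in range(m)]


def _sample_ids(n: int) -> list:
    return [f"s{i + 1}" for i in range(n)]


def mvn_from_template(mean, cov, n: int, seed: int) -> FeatureMatrix:
    """n i.i.d. multivariate-Gaussian draws from a mean/covariance template.

    Marginally indefinite templates are repaired to the nearest PSD matrix
    with a warning; badly indefinite ones are rejected.
    """
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.asarray(cov, dtype=float)
    m = mean.size
    if cov.shape != (m, m):
        raise DataError("mean and covariance dimensions do not match")
    if np.max(np.abs(cov - cov.T)) > 1e-8:
        raise DataError("covariance template must be symmetric")
    cov = (cov + cov.T) / 2.0
    w = np.linalg.eigvalsh(cov)
    scale = max(abs(w[-1]), 1.0)
    if w[0] < -1e-6 * scale:
        raise DataError("covariance template is indefinite")
    if w[0] < 0:
        warnings.warn("covariance template marginally indefinite; repairing", stacklevel=2)
        cov = nearest_psd(cov)
    w, v = np.linalg.eigh(cov)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    x = mean + rng.standard_normal((n, m)) @ factor.T
    return FeatureMatrix(x, _sample_ids(n), _feature_ids(m))


def iid_normal(M: int, n: int, seed: int) -> FeatureMatrix:
    """n draws of M independent standard-normal features."""
    rng = np.random.default_rng(seed)
    return FeatureMatrix(rng.standard_normal((n, M)), _sample_ids(n), _feature_ids(M))


def block_correlated(
    M: int, block_sizes, rho: float, n: int, seed: int
) -> FeatureMatrix:
    """Block-diagonal equicorrelated Gaussian features.

    Each block of size b has equicorrelation rho, with population
    eigenvalues 1 + (b-1)*rho and (b-1) copies of (1-rho).
    """
    block_sizes = [int(b) for b in block_sizes]
    if sum(block_sizes) != M:
        raise DataError("block sizes must sum to M")
    if not (0 <= rho < 1):
        raise DataError("rho must lie in [0, 1)")
    cov = np.zeros((M, M))
    start = 0
    for b in block_sizes:
        cov[start : start + b, start : start + b] = rho
        start += b
    np.fill_diagonal(cov, 1.0)
    return mvn_from_template(np.zeros(M), cov, n, seed)


def nonlinear_pairs(
    n_pairs: int, n: int, noise_sd: float = 0.1, form: str = "square", seed: int = 0
) -> FeatureMatrix:
    """Pairs (X, g(X) + eps) with X standard normal.

    For form="square" the population Pearson correlation within a pair is 0
    by symmetry while the distance correlation is bounded away from zero -
    the dependence structure a linear correlation measure cannot see.
    """
    if n < 50:
        raise DataError("nonlinear_pairs needs n >= 50")
    forms = {
        "square": lambda x: x**2,
        "abs": np.abs,
        "sine": lambda x: np.sin(np.pi * x),
    }
    if form not in forms:
        raise DataError(f"unknown form: {form!r}")
    rng = np.random.default_rng(seed)
    cols = []
    ids = []
    for k in range(n_pairs):
        x = rng.standard_normal(n)
        eps = rng.standard_normal(n) * noise_sd
        cols.append(x)
        cols.append(forms[form](x) + eps)
        ids.extend([f"p{k + 1}_x", f"p{k + 1}_g"])
    return FeatureMatrix(np.column_stack(cols), _sample_ids(n), ids)


def null_outcome(
    n: int, kind: str = "continuous", seed: int = 0, prevalence: float = 0.5
) -> OutcomeVector:
    """Outcome independent of any feature matrix drawn from another seed.

    Binary outcomes have exact counts round(n*prevalence) vs the remainder
    (floor(n/2)/ceil(n/2) at the default prevalence), in a shuffled order.
    """
    if n < 4:
        raise DataError("null_outcome needs n >= 4")
    rng = np.random.default_rng(seed)
    if kind == "continuous":
        return OutcomeVector(rng.standard_normal(n), "continuous")
    if kind == "binary":
        n1 = int(round(n * prevalence))
        if min(n1, n - n1) < 2:
            raise DataError("prevalence too extreme for this n")
        labels = np.array([0] * (n - n1) + [1] * n1)
        rng.shuffle(labels)
        return OutcomeVector(labels, "binary")
    raise DataError(f"unknown outcome kind: {kind!r}")


def random_partition(feature_ids, cardinalities, seed: int, labels=None) -> GroupPartition:
    """Uniform random group assignment with exact group cardinalities."""
    feature_ids = [str(f) for f in feature_ids]
    cardinalities = [int(c) for c in cardinalities]
    if sum(cardinalities) != len(feature_ids):
        raise DataError("cardinalities must sum to the number of features")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(cardinalities))]
    if len(labels) != len(cardinalities):
        raise DataError("labels must match cardinalities")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(feature_ids, dtype=object)[rng.permutation(len(feature_ids))])
    assignment = {}
    pos = 0
    for label, card in zip(labels, cardinalities):
        for f in shuffled[pos : pos + card]:
            assignment[str(f)] = str(label)
        pos += card
    return GroupPartition(assignment)
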