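"""Permutation-based gold standard for the pointwise error rate.

The outcome vector is shuffled K times across samples (feature rows and
covariate rows stay fixed to their samples); for each shuffle all M
per-feature p-values are computed and the minimum stored. The floor(alpha*K)-th
smallest of these K minima estimates the gold-standard pointwise level
alpha_f0, and Meff0 = alpha / alpha_f0.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from scipy import stats

from .feature_tests import _pvalues_from_partial_corr, _welch_from_moments, design_basis
from .types import (
    CovariateTable,
    DataError,
    FeatureMatrix,
    OutcomeVector,
    PermutationGold,
)

log = logging.getLogger(__name__)

__all__ = ["permutation_gold", "gold_ci", "permutation_indices"]


def permutation_indices(seed: int, K: int, n: int) -> np.ndarray:
    """K x n permutation index array, a pure function of the master seed."""
    rng = np.random.default_rng(seed)
    return np.argsort(rng.random((K, n)), axis=1)


def _min_p_regression(X, y, Z, idx, chunk=256):
    n = X.n_samples
    qmat = design_basis(n, Z)
    df = n - 1 - qmat.shape[1]
    if df < 1:
        raise DataError("not enough residual degrees of freedom")
    rx = X.values - qmat @ (qmat.T @ X.values)
    sx = np.linalg.norm(rx, axis=0)
    if np.any(sx <= np.sqrt(np.finfo(float).eps) * np.linalg.norm(X.values, axis=0)):
        raise DataError("feature(s) constant after adjustment")
    rxn = rx / sx
    yv = y.values.astype(float)
    mins = np.empty(idx.shape[0])
    for start in range(0, idx.shape[0], chunk):
        block = idx[start : start + chunk]
        yp = yv[block].T  # n x k
        ry = yp - qmat @ (qmat.T @ yp)
        sy = np.linalg.norm(ry, axis=0)
        sy[sy <= 0] = np.inf
        r = rxn.T @ (ry / sy)  # M x k
        p = _pvalues_from_partial_corr(r, df)
        mins[start : start + block.shape[0]] = p.min(axis=0)
    return mins


def _min_p_welch(X, y, idx, chunk=256):
    lo, hi = y.levels()
    g1 = (y.values == lo).astype(float)
    n1 = int(g1.sum())
    n2 = y.n - n1
    if min(n1, n2) < 2:
        raise DataError("each group needs at least 2 samples")
    xv = X.values
    xsq = xv**2
    mins = np.empty(idx.shape[0])
    for start in range(0, idx.shape[0], chunk):
        block = idx[start : start + chunk]
        b = g1[block].T  # n x k indicator of group 1 after shuffling
        m1 = (xv.T @ b) / n1  # M x k
        m2 = (xv.T @ (1.0 - b)) / n2
        e1 = (xsq.T @ b) / n1
        e2 = (xsq.T @ (1.0 - b)) / n2
        v1 = (e1 - m1**2) * n1 / (n1 - 1)
        v2 = (e2 - m2**2) * n2 / (n2 - 1)
        _, _, p = _welch_from_moments(m1, np.clip(v1, 0, None), n1,
                                      m2, np.clip(v2, 0, None), n2)
        mins[start : start + block.shape[0]] = p.min(axis=0)
    return mins


def permutation_gold(
    X: FeatureMatrix,
    y: OutcomeVector,
    Z: Optional[CovariateTable] = None,
    alpha: float = 0.05,
    K: int = 1000,
    seed: int = 0,
    test: str = "regression",
) -> PermutationGold:
    """Run the K-shuffle gold standard; fully reproducible from ``seed``.

    The order-statistic index is floor(alpha*K) (1-based), exact when
    alpha*K is integral and conservative otherwise.
    """
    if not (0 < alpha < 1):
        raise DataError("alpha must lie in (0, 1)")
    if K < 1:
        raise DataError("K must be >= 1")
    k_idx = int(np.floor(alpha * K))
    if k_idx < 1:
        raise DataError("K too small for requested alpha (floor(alpha*K) < 1)")
    n = X.n_samples
    if y.n != n:
        raise DataError("outcome length does not match sample count")
    if K < n / 2:
        warnings.warn(f"K={K} is below the recommended n/2={n/2:.0f}", stacklevel=2)

    idx = permutation_indices(seed, K, n)
    if test == "regression":
        if y.kind != "continuous":
            raise DataError("regression test needs a continuous outcome")
        if Z is not None and Z.values.shape[0] != n:
            raise DataError("covariate rows do not match sample count")
        mins = _min_p_regression(X, y, Z, idx)
    elif test == "welch":
        if y.kind != "binary":
            raise DataError("welch test needs a binary outcome")
        if Z is not None:
            raise DataError("welch test does not support covariates")
        mins = _min_p_welch(X, y, idx)
    else:
        raise DataError(f"unknown test: {test!r}")

    q = np.sort(mins)
    alpha_f0 = float(q[k_idx - 1])
    if alpha_f0 <= 0:
        alpha_f0 = float(np.finfo(float).tiny)
    meff0 = alpha / alpha_f0
    ci = gold_ci(alpha_f0, K) if 0 < alpha_f0 < 1 else None
    return PermutationGold(
        alpha=alpha, K=K, q=q, alpha_f0=alpha_f0, meff0=meff0, seed=seed, ci=ci
    )


def gold_ci(alpha_f0: float, K: int, level: float = 0.95):
    """Gaussian-approximation binomial CI for the gold-standard level."""
    if not (0 < alpha_f0 < 1):
        raise DataError("alpha_f0 must lie in (0, 1)")
    if K < 30:
        warnings.warn("K < 30: Gaussian binomial approximation is poor", stacklevel=2)
    z = stats.norm.ppf((1.0 + level) / 2.0)
    half = z * np.sqrt(alpha_f0 * (1.0 - alpha_f0) / K)
    lower = max(alpha_f0 - half, float(np.finfo(float).tiny))
    upper = min(alpha_f0 + half, 1.0)
    return (float(lower), float(upper))
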