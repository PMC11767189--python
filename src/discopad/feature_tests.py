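"""Per-feature association tests and covariate residualization.

Continuous outcomes use per-feature linear regression (two-sided t-test on
the feature coefficient, covariate-adjusted when covariates are supplied);
binary outcomes use Welch's two-sample t-test. All tests are vectorized
across the feature columns.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
from scipy import stats

from .types import (
    AdjustedThreshold,
    CovariateTable,
    DataError,
    FeatureMatrix,
    OutcomeVector,
)

log = logging.getLogger(__name__)

__all__ = [
    "design_basis",
    "residualize",
    "regression_pvalues",
    "welch_t_pvalues",
    "significant_features",
]


def design_basis(n: int, Z: Optional[CovariateTable]) -> np.ndarray:
    """Orthonormal basis Q of the column space of [1, Z].

    Raises on rank deficiency, naming the collinear columns.
    """
    if Z is None:
        d = np.ones((n, 1))
        names = ["(intercept)"]
    else:
        if Z.values.shape[0] != n:
            raise DataError("covariate rows do not match sample count")
        d = np.column_stack([np.ones(n), Z.values])
        names = ["(intercept)"] + list(Z.columns)
    q, r = np.linalg.qr(d)
    diag = np.abs(np.diag(r))
    tol = max(d.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise DataError(f"design matrix rank-deficient; collinear columns: {bad}")
    return q


def residualize(X: FeatureMatrix, Z: Optional[CovariateTable]) -> FeatureMatrix:
    """Replace each feature by its least-squares residual on [1, Z].

    With no covariates this is plain mean-centering. Residuals are
    orthogonal to the intercept and every covariate column.
    """
    n = X.n_samples
    q = design_basis(n, Z)
    if n <= q.shape[1]:
        raise DataError("need more samples than design columns")
    resid = X.values - q @ (q.T @ X.values)
    return FeatureMatrix(resid, X.sample_ids, X.feature_ids)


def _pvalues_from_partial_corr(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t2 = df * r**2 / (1.0 - r**2)
    t = np.sqrt(np.where(np.isfinite(t2), t2, np.inf))
    p = 2.0 * stats.t.sf(t, df)
    return np.clip(p, 0.0, 1.0)


def regression_pvalues(
    X: FeatureMatrix,
    y: OutcomeVector,
    Z: Optional[CovariateTable] = None,
) -> np.ndarray:
    """Two-sided p-value for the feature coefficient in y ~ 1 + feature (+ Z).

    Computed via the partial-correlation identity: residualize both y and
    the features on [1, Z], then t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - q, which matches the per-feature OLS t-test exactly.
    Features with zero variance after adjustment get p = 1 (with a warning).
    """
    if y.kind != "continuous":
        raise DataError("regression_pvalues expects a continuous outcome")
    n = X.n_samples
    if y.n != n:
        raise DataError("outcome length does not match sample count")
    qmat = design_basis(n, Z)
    df = n - 1 - qmat.shape[1]
    if df < 1:
        raise DataError("not enough residual degrees of freedom")
    rx = X.values - qmat @ (qmat.T @ X.values)
    ry = y.values - qmat @ (qmat.T @ y.values)
    sx = np.linalg.norm(rx, axis=0)
    sy = float(np.linalg.norm(ry))
    # relative tolerance: a feature projected (numerically) into the design
    # span is constant after adjustment
    dead = sx <= np.sqrt(np.finfo(float).eps) * np.linalg.norm(X.values, axis=0)
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} feature(s) constant after adjustment; p set to 1",
            stacklevel=2,
        )
    if sy <= np.sqrt(np.finfo(float).eps) * np.linalg.norm(y.values):
        warnings.warn("outcome constant after adjustment; all p set to 1", stacklevel=2)
        return np.ones(X.n_features)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx.T @ ry) / np.where(dead, 1.0, sx) / sy
    p = _pvalues_from_partial_corr(r, df)
    p[dead] = 1.0
    return p


def _welch_from_moments(m1, v1, n1, m2, v2, n2):
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = np.where(se2 > 0, t, 0.0)
    df = np.where(se2 > 0, df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, np.clip(p, 0.0, 1.0)


def welch_t_pvalues(X: FeatureMatrix, y: OutcomeVector, full: bool = False):
    """Welch's two-sample t-test per feature for a binary outcome.

    Group 1 is the lexicographically (or numerically) smaller outcome level.
    Returns the p-value vector, or (t, df, p) when ``full`` is True.
    """
    if y.kind != "binary":
        raise DataError("welch_t_pvalues expects a binary outcome")
    if y.n != X.n_samples:
        raise DataError("outcome length does not match sample count")
    lo, hi = y.levels()
    g1 = y.values == lo
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if min(n1, n2) < 2:
        raise DataError("each group needs at least 2 samples")
    x1, x2 = X.values[g1], X.values[~g1]
    t, df, p = _welch_from_moments(
        x1.mean(axis=0), x1.var(axis=0, ddof=1), n1,
        x2.mean(axis=0), x2.var(axis=0, ddof=1), n2,
    )
    return (t, df, p) if full else p


def significant_features(p: np.ndarray, threshold: AdjustedThreshold, feature_ids=None):
    """Features with p <= pwer (boundary inclusive), sorted by p ascending.

    Returns (count, ordered feature-id list).
    """
    p = np.asarray(p, dtype=float)
    if feature_ids is None:
        feature_ids = [str(i) for i in range(p.size)]
    if len(feature_ids) != p.size:
        raise DataError("feature_ids length does not match p-value vector")
    hits = np.nonzero(p <= threshold.pwer)[0]
    order = hits[np.argsort(p[hits], kind="stable")]
    return int(order.size), [str(feature_ids[i]) for i in order]
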