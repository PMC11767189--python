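"""Pairwise association matrices: Pearson, Spearman, and distance correlation.

Distance covariance is the empirical V-statistic: with a_ij = |x_i - x_j| and
b_ij = |y_i - y_j|, double-center each matrix (subtract row and column means,
add the grand mean) and average the elementwise product,

    V^2(x, y) = (1/n^2) * sum_ij A_ij * B_ij,   dcov = sqrt(V^2).

Two engines are provided: a direct double-centering implementation
(``dcov_naive``) and an O(n log n) univariate algorithm (``dcov_fast``) that
must agree with the naive one to 1e-10 on all inputs, including ties.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import AssociationMatrix, DataError, FeatureMatrix

__all__ = [
    "pearson_matrix",
    "spearman_matrix",
    "dcov_naive",
    "dvar",
    "dcor",
    "dcov_fast",
    "distance_matrix",
    "correlation_matrix",
]


def _check_nonconstant(X: FeatureMatrix) -> None:
    bad = X.constant_features()
    if bad:
        raise DataError(
            f"zero-variance feature(s) not allowed here: {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )


def _corrcoef(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(values, rowvar=False)
    c = np.atleast_2d(c)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def pearson_matrix(X: FeatureMatrix) -> AssociationMatrix:
    """Signed product-moment correlation matrix of the features."""
    _check_nonconstant(X)
    return AssociationMatrix(_corrcoef(X.values), "pearson", X.feature_ids)


def spearman_matrix(X: FeatureMatrix) -> AssociationMatrix:
    """Pearson correlation of mid-ranks (average ranks for ties)."""
    _check_nonconstant(X)
    ranks = rankdata(X.values, axis=0, method="average")
    return AssociationMatrix(_corrcoef(ranks), "spearman", X.feature_ids)


# ---------------------------------------------------------------------------
# distance covariance / correlation
# ---------------------------------------------------------------------------


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 2:
        raise DataError("distance covariance needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in input")
    return x, y


def _centered_dist(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0)[None, :] - d.mean(axis=1)[:, None] + d.mean()


def dcov_naive(x, y) -> float:
    """Empirical distance covariance by direct double-centering, O(n^2)."""
    x, y = _validate_pair(x, y)
    v2 = float(np.mean(_centered_dist(x) * _centered_dist(y)))
    return float(np.sqrt(max(v2, 0.0)))


def dvar(x) -> float:
    """Distance variance: dcov(x, x). Zero iff x is constant."""
    x = np.asarray(x, dtype=float).ravel()
    return dcov_naive(x, x)


def dcor(x, y) -> float:
    """Distance correlation in [0, 1]; 0 when either input is constant."""
    x, y = _validate_pair(x, y)
    vx = dcov_naive(x, x) ** 2
    vy = dcov_naive(y, y) ** 2
    denom = vx * vy
    if denom <= 0.0:
        return 0.0
    r2 = dcov_naive(x, y) ** 2 / np.sqrt(denom)
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def _abs_dist_row_sums(v: np.ndarray) -> np.ndarray:
    """Row sums of the |v_i - v_j| distance matrix in O(n log n)."""
    n = v.size
    order = np.argsort(v, kind="stable")
    vs = v[order]
    pre = np.concatenate(([0.0], np.cumsum(vs)[:-1]))
    total = float(vs.sum())
    rows = (2.0 * np.arange(n) - n) * vs + total - 2.0 * pre
    out = np.empty(n)
    out[order] = rows
    return out


def _sum_abs_prod(x: np.ndarray, y: np.ndarray) -> float:
    """sum_ij |x_i - x_j| * |y_i - y_j| in O(n log n).

    Sort by x; then for j > i the x-distance is (x_j - x_i) >= 0, and the
    y-distance sign is resolved with a Fenwick tree over y-ranks that
    accumulates counts and partial sums of x, y and x*y. Pairs tied in
    either coordinate contribute exactly zero, so tie placement is free.
    """
    n = x.size
    order = np.lexsort((y, x))
    xs = x[order]
    ys = y[order]
    # dense 1-based ranks of ys (ties share a rank)
    uniq, ry = np.unique(ys, return_inverse=True)
    ry = ry + 1
    size = uniq.size

    tc = [0.0] * (size + 1)
    tx = [0.0] * (size + 1)
    ty = [0.0] * (size + 1)
    txy = [0.0] * (size + 1)

    tot_c = 0.0
    tot_x = 0.0
    tot_y = 0.0
    tot_xy = 0.0
    total = 0.0

    for j in range(n):
        xj = xs[j]
        yj = ys[j]
        r = int(ry[j])
        cL = 0.0
        sxL = 0.0
        syL = 0.0
        sxyL = 0.0
        k = r
        while k > 0:
            cL += tc[k]
            sxL += tx[k]
            syL += ty[k]
            sxyL += txy[k]
            k -= k & -k
        xy = xj * yj
        # i < j with y_i <= y_j: both distances nonnegative
        tL = xy * cL - xj * syL - yj * sxL + sxyL
        # i < j with y_i > y_j: flip the sign of the y-distance
        tG = (
            xy * (tot_c - cL)
            - xj * (tot_y - syL)
            - yj * (tot_x - sxL)
            + (tot_xy - sxyL)
        )
        total += tL - tG
        k = r
        while k <= size:
            tc[k] += 1.0
            tx[k] += xj
            ty[k] += yj
            txy[k] += xy
            k += k & -k
        tot_c += 1.0
        tot_x += xj
        tot_y += yj
        tot_xy += xy

    return 2.0 * total


def dcov_fast(x, y) -> float:
    """O(n log n) empirical distance covariance for univariate x and y.

    Agrees with :func:`dcov_naive` to 1e-10 relative tolerance, ties and
    constant inputs included.
    """
    x, y = _validate_pair(x, y)
    n = x.size
    ax = _abs_dist_row_sums(x)
    ay = _abs_dist_row_sums(y)
    s1 = _sum_abs_prod(x, y) / n**2
    s2 = float(ax @ ay) / n**3
    s3 = float(ax.sum()) * float(ay.sum()) / n**4
    v2 = s1 - 2.0 * s2 + s3
    return float(np.sqrt(max(v2, 0.0)))


def _distance_gram(values: np.ndarray, block: int = 64) -> np.ndarray:
    """M x M matrix of squared distance covariances via centered-matrix Gram.

    Flattens each feature's double-centered distance matrix and takes inner
    products, so V^2(i, j) = <A_i, B_j> / n^2 for every pair at once.
    Features are processed in blocks to bound memory at block * n^2 doubles.
    """
    n, m = values.shape
    flat = np.empty((m, n * n))
    for start in range(0, m, block):
        stop = min(start + block, m)
        for j in range(start, stop):
            flat[j] = _centered_dist(values[:, j]).ravel()
    return (flat @ flat.T) / n**2


def distance_matrix(X: FeatureMatrix, engine: str = "naive") -> AssociationMatrix:
    """Pairwise distance-correlation matrix over all feature pairs.

    engine="naive" vectorizes the double-centering estimator across pairs
    (memory ~ block * n^2); engine="fast" uses the O(n log n) algorithm per
    pair and is preferred for large n.
    """
    _check_nonconstant(X)
    m = X.n_features
    if engine == "naive":
        v2 = _distance_gram(X.values)
    elif engine == "fast":
        v2 = np.zeros((m, m))
        cols = [np.ascontiguousarray(X.values[:, j]) for j in range(m)]
        for i in range(m):
            v2[i, i] = dcov_fast(cols[i], cols[i]) ** 2
        for i in range(m):
            for j in range(i + 1, m):
                v2[i, j] = v2[j, i] = dcov_fast(cols[i], cols[j]) ** 2
    else:
        raise ValueError(f"unknown engine: {engine!r}")

    dv = np.diag(v2).copy()
    if np.any(dv <= 0):
        bad = [X.feature_ids[i] for i in np.nonzero(dv <= 0)[0]]
        raise DataError(f"zero distance variance for feature(s): {bad}")
    r2 = v2 / np.sqrt(np.outer(dv, dv))
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return AssociationMatrix(r, "distance", X.feature_ids)


def correlation_matrix(
    X: FeatureMatrix, method: str, engine: str = "naive"
) -> AssociationMatrix:
    """Dispatch to the requested association-matrix builder."""
    if method == "pearson":
        return pearson_matrix(X)
    if method == "spearman":
        return spearman_matrix(X)
    if method == "distance":
        return distance_matrix(X, engine=engine)
    raise ValueError(f"unknown correlation method: {method!r}")
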