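"""Effective-number-of-tests estimators and single-step threshold adjustment.

Five eigen-analysis estimators (Nyholt, Li-Ji, Gao, Galwey, Peluso) operate
on the floored eigenvalue spectrum of a feature association matrix; the
Bonferroni/Sidak baselines use the raw feature count. The resulting Meff
feeds a Bonferroni-type (alpha/Meff) or Sidak-type (1-(1-alpha)^(1/Meff))
pointwise threshold.
"""
from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np

from .assoc import correlation_matrix
from .psd import DEFAULT_FLOOR, eigenvalues, is_psd, nearest_psd
from .types import (
    AdjustedThreshold,
    AssociationMatrix,
    DataError,
    EigenSpectrum,
    FeatureMatrix,
    GroupPartition,
    MeffEstimate,
)

log = logging.getLogger(__name__)

__all__ = [
    "meff_nyholt",
    "meff_liji",
    "meff_gao",
    "meff_galwey",
    "meff_peluso",
    "meff_baseline",
    "estimate_from_spectrum",
    "adjusted_pwer",
    "effective_tests_from_pwer",
    "spectrum_from_matrix",
    "meff_from_matrix",
    "meff_grouped",
    "disco_pad",
]


def meff_nyholt(spec: EigenSpectrum) -> float:
    """1 + (M-1) * (1 - var(lambda)/M), sample variance (M-1 denominator)."""
    if spec.M < 2:
        raise DataError("nyholt needs at least 2 eigenvalues")
    var = float(np.var(spec.values, ddof=1))
    return float(1.0 + (spec.M - 1) * (1.0 - var / spec.M))


def meff_liji(spec: EigenSpectrum) -> float:
    """sum of f(|lambda_i|) with f(x) = I(x >= 1) + (x - floor(x)).

    f is discontinuous at integers, so eigenvalues within 1e-9 of an integer
    are snapped to it first; otherwise an exactly-duplicated feature whose
    eigenvalue computes as 2 - 1e-16 would contribute ~2 instead of f(2) = 1.
    """
    a = np.abs(spec.values)
    nearest = np.round(a)
    a = np.where(np.abs(a - nearest) < 1e-9, nearest, a)
    return float(np.sum((a >= 1.0).astype(float) + (a - np.floor(a))))


def meff_gao(spec: EigenSpectrum, C: float = 0.995) -> int:
    """Smallest k with the top-k eigenvalues explaining >= C of the total."""
    total = float(spec.values.sum())
    if total <= 0:
        raise DataError("gao undefined for an all-zero spectrum")
    cum = np.cumsum(spec.values) / total
    return int(np.argmax(cum >= C) + 1)


def meff_galwey(spec: EigenSpectrum) -> float:
    """(sum sqrt(lambda))^2 / sum(lambda), negatives floored upstream."""
    lam = np.clip(spec.values, 0.0, None)
    total = float(lam.sum())
    if total <= 0:
        raise DataError("galwey undefined for an all-zero spectrum")
    return float(np.sum(np.sqrt(lam)) ** 2 / total)


def meff_peluso(spec: EigenSpectrum, lam: str = "max") -> float:
    """(sum sqrt(lambda_i) / log(lambda_ref))^2 / (sum lambda_i/lambda_ref + lambda_ref).

    ``lam`` selects the reference eigenvalue: "max" (default; the only
    reading that can yield Meff > M, matching the reported behavior of the
    estimator) or "min" (the literal ascending-index convention).
    """
    if lam == "max":
        ref = float(spec.values[0])
        if ref <= 1.0:
            raise DataError("peluso undefined for this spectrum (lambda_max <= 1)")
    elif lam == "min":
        ref = float(spec.values[-1])
        if ref <= 0.0 or ref == 1.0:
            raise DataError("peluso undefined for this spectrum (log lambda_min)")
    else:
        raise ValueError(f"unknown peluso lambda convention: {lam!r}")
    vals = np.clip(spec.values, 0.0, None)
    num = float(np.sum(np.sqrt(vals)) / np.log(ref)) ** 2
    den = float(np.sum(vals) / ref + ref)
    return num / den


_EIGEN_DISPATCH = {
    "nyholt": meff_nyholt,
    "liji": meff_liji,
    "gao": meff_gao,
    "galwey": meff_galwey,
    "peluso": meff_peluso,
}


def estimate_from_spectrum(
    spec: EigenSpectrum, estimator: str, *, gao_c: float = 0.995, peluso_lambda: str = "max"
) -> float:
    """Evaluate one eigen-analysis estimator on a spectrum."""
    if estimator == "gao":
        return float(meff_gao(spec, C=gao_c))
    if estimator == "peluso":
        return meff_peluso(spec, lam=peluso_lambda)
    if estimator in _EIGEN_DISPATCH:
        return float(_EIGEN_DISPATCH[estimator](spec))
    raise DataError(f"not an eigen-analysis estimator: {estimator!r}")


def meff_baseline(M: int, estimator: str) -> MeffEstimate:
    """Bonferroni/Sidak baselines: Meff is the raw test count M."""
    if estimator not in ("bonferroni", "sidak"):
        raise DataError(f"not a baseline estimator: {estimator!r}")
    if M < 1:
        raise DataError("M must be >= 1")
    return MeffEstimate(estimator=estimator, value=float(M), corr_method="none")


def adjusted_pwer(alpha: float, meff: float, style: str) -> AdjustedThreshold:
    """Pointwise level from a family-wise level and an effective test count."""
    if not (0 < alpha < 1):
        raise DataError("alpha must lie in (0, 1)")
    if not (meff >= 1):
        raise DataError("meff must be >= 1")
    if style == "bonferroni-type":
        pwer = alpha / meff
    elif style == "sidak-type":
        pwer = 1.0 - (1.0 - alpha) ** (1.0 / meff)
    else:
        raise DataError(f"unknown adjustment style: {style!r}")
    # guard against fp overshoot at meff == 1 (pwer must not exceed alpha)
    return AdjustedThreshold(alpha=alpha, style=style, pwer=float(min(pwer, alpha)))


def effective_tests_from_pwer(alpha: float, pwer: float) -> float:
    """alpha / pwer: the effective test count implied by a pointwise level."""
    if not (0 < alpha < 1):
        raise DataError("alpha must lie in (0, 1)")
    if not (0 < pwer <= alpha):
        raise DataError("pwer must lie in (0, alpha]")
    return float(alpha / pwer)


# ---------------------------------------------------------------------------
# pipeline: association matrix -> repaired spectrum -> estimate -> threshold
# ---------------------------------------------------------------------------


def spectrum_from_matrix(
    A: AssociationMatrix,
    floor: float = DEFAULT_FLOOR,
    renormalize_diagonal: bool = False,
) -> EigenSpectrum:
    """PSD-repair an association matrix (if needed) and extract its spectrum."""
    if not is_psd(A):
        log.info("association matrix (%s) not PSD; applying nearest-PSD repair", A.method)
        A = nearest_psd(A)
        if renormalize_diagonal:
            d = np.sqrt(np.clip(np.diag(A.entries), 1e-300, None))
            A = AssociationMatrix(
                A.entries / np.outer(d, d), A.method, A.feature_ids
            )
    return eigenvalues(A, floor=floor)


def meff_from_matrix(
    A: AssociationMatrix,
    estimator: str,
    *,
    floor: float = DEFAULT_FLOOR,
    gao_c: float = 0.995,
    peluso_lambda: str = "max",
    renormalize_diagonal: bool = False,
) -> MeffEstimate:
    """Single-group Meff estimate straight from an association matrix."""
    if estimator in ("bonferroni", "sidak"):
        est = meff_baseline(A.n_features, estimator)
        return MeffEstimate(estimator, est.value, corr_method="none")
    spec = spectrum_from_matrix(A, floor=floor, renormalize_diagonal=renormalize_diagonal)
    value = estimate_from_spectrum(
        spec, estimator, gao_c=gao_c, peluso_lambda=peluso_lambda
    )
    return MeffEstimate(estimator, value, corr_method=A.method)


def _group_value(A_sub: AssociationMatrix, estimator: str, **kw) -> float:
    """Per-group estimate with documented singleton/degenerate fallbacks."""
    if A_sub.n_features == 1:
        if estimator in ("nyholt", "peluso"):
            warnings.warn(
                f"{estimator}: singleton group contributes 1 by convention",
                stacklevel=3,
            )
        return 1.0
    return meff_from_matrix(A_sub, estimator, **kw).value


def grouped_from_matrix(
    A: AssociationMatrix,
    partition: GroupPartition,
    estimator: str,
    **kw,
) -> MeffEstimate:
    """Sum of per-group estimates, each from its own PSD-repaired submatrix."""
    partition.validate_against(A.feature_ids)
    per_group = {}
    for label in partition.labels():
        sub = A.submatrix(partition.members(label))
        per_group[label] = _group_value(sub, estimator, **kw)
    total = float(sum(per_group.values()))
    return MeffEstimate(estimator, total, corr_method=A.method, per_group=per_group)


def meff_grouped(
    X: FeatureMatrix,
    partition: GroupPartition,
    corr_method: str,
    estimator: str,
    *,
    engine: str = "naive",
    **kw,
) -> MeffEstimate:
    """Grouped Meff from raw features: per-group correlation submatrices,
    independently repaired and floored, estimates summed across groups."""
    if estimator in ("bonferroni", "sidak"):
        return meff_baseline(X.n_features, estimator)
    A = correlation_matrix(X, corr_method, engine=engine)
    return grouped_from_matrix(A, partition, estimator, **kw)


def disco_pad(
    X: FeatureMatrix,
    estimator: str,
    alpha: float = 0.05,
    style: str = "sidak-type",
    partition: Optional[GroupPartition] = None,
    corr_method: str = "distance",
    *,
    engine: str = "naive",
    floor: float = DEFAULT_FLOOR,
    gao_c: float = 0.995,
    peluso_lambda: str = "max",
    renormalize_diagonal: bool = False,
):
    """End-to-end p-value-adjustment pipeline.

    correlation matrix -> nearest-PSD repair -> floored eigenvalues ->
    Meff estimator -> pointwise threshold. With corr_method="pearson" this
    is the Pearson-correlation branch of the same pipeline.

    Returns
    -------
    (MeffEstimate, AdjustedThreshold)
    """
    kw = dict(
        floor=floor,
        gao_c=gao_c,
        peluso_lambda=peluso_lambda,
        renormalize_diagonal=renormalize_diagonal,
    )
    if estimator in ("bonferroni", "sidak"):
        est = meff_baseline(X.n_features, estimator)
    elif partition is None:
        A = correlation_matrix(X, corr_method, engine=engine)
        est = meff_from_matrix(A, estimator, **kw)
    else:
        est = meff_grouped(
            X, partition, corr_method, estimator, engine=engine, **kw
        )
    thr = adjusted_pwer(alpha, max(est.value, 1.0), style)
    return est, thr
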