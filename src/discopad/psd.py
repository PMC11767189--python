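"""Positive-semidefinite testing and repair, plus eigenvalue extraction.

Empirical distance-correlation matrices need not be positive semidefinite;
before eigen-analysis they are projected (in Frobenius norm) onto the PSD
cone by clipping negative eigenvalues to zero. Eigenvalues below a small
floor (default 1e-12) are then set to exactly zero.
"""
from __future__ import annotations

import logging

import numpy as np

from .types import AssociationMatrix, DataError, EigenSpectrum

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8
DEFAULT_FLOOR = 1e-12

__all__ = ["is_psd", "nearest_psd", "eigenvalues"]


def _entries(A) -> np.ndarray:
    e = A.entries if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise DataError("matrix must be square")
    if not np.all(np.isfinite(e)):
        raise DataError("matrix contains non-finite entries")
    asym = np.max(np.abs(e - e.T)) if e.size else 0.0
    if asym > SYMMETRY_TOL:
        raise DataError(f"matrix asymmetric beyond {SYMMETRY_TOL:g} (got {asym:.3g})")
    return (e + e.T) / 2.0


def is_psd(A, tol: float = 1e-10) -> bool:
    """True iff the smallest eigenvalue of (A + A^T)/2 is >= -tol."""
    w = np.linalg.eigvalsh(_entries(A))
    return bool(w[0] >= -tol)


def nearest_psd(A: AssociationMatrix) -> AssociationMatrix:
    """Frobenius-nearest symmetric PSD matrix (eigenvalue clipping).

    Already-PSD inputs are returned unchanged. Otherwise negative
    eigenvalues are set to zero and the matrix reconstructed; a minimal
    diagonal jitter is added only if the finite-precision check still
    fails after clipping. The unit diagonal is NOT restored afterwards
    (any drift is logged).
    """
    e = _entries(A)
    if is_psd(e, tol=1e-12):
        return A
    w, v = np.linalg.eigh(e)
    clipped = int(np.sum(w < 0))
    b = (v * np.clip(w, 0.0, None)) @ v.T
    b = (b + b.T) / 2.0
    jitter = 0.0
    while np.linalg.eigvalsh(b)[0] < -1e-12:  # finite-precision safety net
        jitter = max(jitter * 10.0, 1e-15)
        b = b + jitter * np.eye(b.shape[0])
        b = (b + b.T) / 2.0
    drift = float(np.max(np.abs(np.diag(b) - np.diag(e)))) if b.size else 0.0
    log.info(
        "nearest_psd: clipped %d negative eigenvalue(s); max diagonal drift %.3g",
        clipped,
        drift,
    )
    if isinstance(A, AssociationMatrix):
        return AssociationMatrix(b, A.method, A.feature_ids)
    return b


def eigenvalues(A, floor: float = DEFAULT_FLOOR) -> EigenSpectrum:
    """Full symmetric eigendecomposition with flooring.

    Eigenvalues below ``floor`` are replaced by exactly zero; the spectrum
    is returned sorted descending.
    """
    w = np.linalg.eigvalsh(_entries(A))
    floored = w < floor
    w = np.where(floored, 0.0, w)
    n_floored = int(np.sum(floored))
    if n_floored:
        log.info("eigenvalues: floored %d value(s) below %.3g", n_floored, floor)
    return EigenSpectrum(np.sort(w)[::-1], floor_applied=bool(n_floored))
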