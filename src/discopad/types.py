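"""Core value types shared across the discopad pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

CORR_METHODS = ("pearson", "spearman", "distance")
EIGEN_ESTIMATORS = ("nyholt", "liji", "gao", "galwey", "peluso")
BASELINE_ESTIMATORS = ("bonferroni", "sidak")
ESTIMATORS = BASELINE_ESTIMATORS + EIGEN_ESTIMATORS
STYLES = ("bonferroni-type", "sidak-type")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _as_str_list(labels: Sequence) -> list:
    return [str(x) for x in labels]


@dataclass
class FeatureMatrix:
    """An n-samples by M-features numeric abundance table.

    Values are assumed to be log-transformed (and, where applicable,
    covariate-residualized) abundances. Missing values are not allowed here;
    missing-data handling happens at the IO/join layer.
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_list(self.sample_ids)
        self.feature_ids = _as_str_list(self.feature_ids)
        if self.values.ndim != 2:
            raise DataError("feature matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 2:
            raise DataError("at least 2 samples are required")
        if m < 1:
            raise DataError("at least 1 feature is required")
        if len(self.sample_ids) != n or len(self.feature_ids) != m:
            raise DataError("id lengths do not match matrix shape")
        if len(set(self.feature_ids)) != m:
            raise DataError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(str(feature_id))]

    def select(self, feature_ids: Sequence) -> "FeatureMatrix":
        """Column subset preserving sample order."""
        wanted = _as_str_list(feature_ids)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise DataError(f"unknown feature ids: {missing}")
        cols = [index[f] for f in wanted]
        return FeatureMatrix(self.values[:, cols], self.sample_ids, wanted)

    def constant_features(self, tol: float = 0.0) -> list:
        """Ids of features with (near-)zero variance."""
        ptp = self.values.max(axis=0) - self.values.min(axis=0)
        return [f for f, p in zip(self.feature_ids, ptp) if p <= tol]


@dataclass
class AssociationMatrix:
    """M x M symmetric pairwise-association matrix tagged with its method."""

    entries: np.ndarray
    method: str
    feature_ids: list

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.feature_ids = _as_str_list(self.feature_ids)
        if self.method not in CORR_METHODS:
            raise DataError(f"unknown association method: {self.method!r}")
        m = len(self.feature_ids)
        if self.entries.shape != (m, m):
            raise DataError("entries shape does not match feature_ids")
        if not np.all(np.isfinite(self.entries)):
            raise DataError("association matrix contains non-finite values")
        asym = np.max(np.abs(self.entries - self.entries.T)) if m else 0.0
        if asym > 1e-8:
            raise DataError(f"matrix is asymmetric beyond tolerance ({asym:.3g})")
        # force exact symmetry so downstream eigh sees one canonical matrix
        self.entries = (self.entries + self.entries.T) / 2.0

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def submatrix(self, feature_ids: Sequence) -> "AssociationMatrix":
        wanted = _as_str_list(feature_ids)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in wanted if f not in index]
        if missing:
            raise DataError(f"unknown feature ids: {missing}")
        cols = np.array([index[f] for f in wanted])
        return AssociationMatrix(self.entries[np.ix_(cols, cols)], self.method, wanted)


@dataclass
class EigenSpectrum:
    """Eigenvalues of an association matrix after repair and flooring.

    Stored sorted in descending order (the cumulative-variance estimator
    needs the top of the spectrum first).
    """

    values: np.ndarray
    floor_applied: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise DataError("spectrum must be a non-empty vector")
        if np.any(np.diff(self.values) > 0):
            self.values = np.sort(self.values)[::-1].copy()

    @property
    def M(self) -> int:
        return self.values.size


@dataclass
class MeffEstimate:
    """An effective-number-of-tests estimate."""

    estimator: str
    value: float
    corr_method: str = "none"
    per_group: Optional[dict] = None

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise DataError(f"unknown estimator: {self.estimator!r}")
        if not (self.value > 0):
            raise DataError("Meff must be positive")


@dataclass
class AdjustedThreshold:
    """A family-wise level alpha and the pointwise level that achieves it."""

    alpha: float
    style: str
    pwer: float

    def __post_init__(self):
        if self.style not in STYLES:
            raise DataError(f"unknown adjustment style: {self.style!r}")
        if not (0 < self.alpha < 1):
            raise DataError("alpha must lie in (0, 1)")
        if not (0 < self.pwer <= self.alpha):
            raise DataError("pointwise level must lie in (0, alpha]")


@dataclass
class OutcomeVector:
    """Per-sample outcome: continuous values or a two-level label."""

    values: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise DataError(f"unknown outcome kind: {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise DataError("outcome must be a vector")
        if self.kind == "continuous":
            self.values = self.values.astype(float)
            if not np.all(np.isfinite(self.values)):
                raise DataError("continuous outcome contains non-finite values")
        else:
            levels, counts = np.unique(self.values, return_counts=True)
            if levels.size != 2:
                raise DataError(
                    f"binary outcome must have exactly 2 levels, got {levels.size}"
                )
            if counts.min() < 2:
                raise DataError("each binary outcome level needs >= 2 samples")

    @property
    def n(self) -> int:
        return self.values.size

    def levels(self) -> np.ndarray:
        """The two levels, sorted ascending; the first one is 'group 1'."""
        if self.kind != "binary":
            raise DataError("levels() only applies to binary outcomes")
        return np.unique(self.values)


@dataclass
class CovariateTable:
    """n x q numeric covariate matrix (categoricals pre-encoded)."""

    values: np.ndarray
    columns: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        self.columns = _as_str_list(self.columns)
        if self.values.shape[1] != len(self.columns):
            raise DataError("covariate column labels do not match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise DataError("covariate table contains non-finite values")

    @property
    def q(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupPartition:
    """A disjoint, covering assignment of feature ids to group labels."""

    assignment: Mapping[str, str]

    def __post_init__(self):
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}

    def labels(self) -> list:
        seen: dict = {}
        for g in self.assignment.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, label: str) -> list:
        return [f for f, g in self.assignment.items() if g == str(label)]

    def cardinalities(self) -> dict:
        out: dict = {}
        for g in self.assignment.values():
            out[g] = out.get(g, 0) + 1
        return out

    def validate_against(self, feature_ids: Sequence) -> None:
        wanted = set(_as_str_list(feature_ids))
        got = set(self.assignment)
        if got != wanted:
            missing = sorted(wanted - got)[:5]
            extra = sorted(got - wanted)[:5]
            raise DataError(
                f"partition does not cover the feature set (missing={missing}, extra={extra})"
            )


@dataclass
class PermutationGold:
    """Permutation gold standard for the pointwise error rate."""

    alpha: float
    K: int
    q: np.ndarray  # the K minimum p-values, sorted ascending
    alpha_f0: float
    meff0: float
    seed: int
    ci: Optional[tuple] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.size != self.K:
            raise DataError("q must hold exactly K minimum p-values")
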