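"""Delimited-text ingestion and serialization.

All formats are plain text: TSV/CSV for feature tables, metadata,
association matrices, group maps and p-value tables; JSON for results.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    AssociationMatrix,
    CovariateTable,
    DataError,
    FeatureMatrix,
    GroupPartition,
    OutcomeVector,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_association_matrix",
    "write_association_matrix",
    "read_group_map",
    "read_metadata",
    "align_samples",
    "filter_features",
]


def _read_df(path, delimiter="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#",
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise DataError(f"duplicate row ids in {path}: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][:5].tolist()
        raise DataError(f"duplicate column ids in {path}: {dup}")
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    if out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise DataError(
            f"missing value in {path} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_feature_table(
    path, orientation: str = "samples-by-features", delimiter: str = "\t"
) -> FeatureMatrix:
    """Read a numeric feature table with a header row and an id column."""
    df = _read_df(path, delimiter)
    if orientation == "features-by-samples":
        df = df.T
    elif orientation != "samples-by-features":
        raise DataError(f"unknown orientation: {orientation!r}")
    df = _to_numeric(df, path)
    return FeatureMatrix(df.to_numpy(float), list(df.index), list(df.columns))


def write_feature_table(X: FeatureMatrix, path, delimiter: str = "\t") -> None:
    pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids).to_csv(
        path, sep=delimiter, index_label="sample_id", float_format="%.17g"
    )


def write_association_matrix(A: AssociationMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# method={A.method}\n")
        pd.DataFrame(A.entries, index=A.feature_ids, columns=A.feature_ids).to_csv(
            fh, sep=delimiter, index_label="feature_id", float_format="%.17g"
        )


def read_association_matrix(path, delimiter: str = "\t", method: Optional[str] = None):
    if method is None:
        with open(path) as fh:
            first = fh.readline().strip()
        if first.startswith("#") and "method=" in first:
            method = first.split("method=")[1].strip()
        else:
            raise DataError("association matrix file lacks a '# method=' header")
    df = _to_numeric(_read_df(path, delimiter), path)
    if list(df.index) != list(df.columns):
        raise DataError("association matrix row/column ids differ")
    return AssociationMatrix(df.to_numpy(float), method, list(df.index))


def read_group_map(path, feature_ids=None, allow_ungrouped: bool = False,
                   delimiter: str = "\t") -> GroupPartition:
    """Two-column (feature_id, group) map -> GroupPartition.

    Features absent from the map are an error in strict mode; with
    ``allow_ungrouped`` each becomes its own singleton group.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError("group map needs two columns: feature_id, group")
    feats = df.iloc[:, 0].astype(str)
    if feats.duplicated().any():
        dup = feats[feats.duplicated()].tolist()[:5]
        raise DataError(f"duplicate feature rows in group map: {dup}")
    assignment = dict(zip(feats, df.iloc[:, 1].astype(str)))
    if feature_ids is not None:
        wanted = [str(f) for f in feature_ids]
        missing = [f for f in wanted if f not in assignment]
        if missing and not allow_ungrouped:
            raise DataError(
                f"{len(missing)} feature(s) absent from group map (strict mode): "
                f"{missing[:5]}"
            )
        for f in missing:
            assignment[f] = f"__singleton_{f}"
        assignment = {f: assignment[f] for f in wanted}
    return GroupPartition(assignment)


def read_metadata(path, delimiter: str = "\t") -> pd.DataFrame:
    """Sample metadata table indexed by sample id; missing values allowed."""
    return _read_df(path, delimiter)


def align_samples(
    X: FeatureMatrix,
    metadata: pd.DataFrame,
    outcome: str,
    covariates: Sequence = (),
    outcome_kind: str = "continuous",
):
    """Join features with metadata on sample id, dropping samples with a
    missing outcome or missing covariates (the count is logged).

    Returns (FeatureMatrix, OutcomeVector, CovariateTable | None, n_dropped).
    """
    cols = [outcome] + list(covariates)
    for c in cols:
        if c not in metadata.columns:
            raise DataError(f"metadata lacks column {c!r}")
    meta = metadata.copy()
    meta.index = meta.index.astype(str)
    missing_ids = [s for s in X.sample_ids if s not in meta.index]
    if missing_ids:
        raise DataError(f"metadata lacks sample(s): {missing_ids[:5]}")
    meta = meta.loc[X.sample_ids, cols]
    keep = meta.notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("align_samples: dropped %d sample(s) with missing outcome/covariates",
                 n_dropped)
    values = X.values[keep]
    sample_ids = [s for s, k in zip(X.sample_ids, keep) if k]
    Xk = FeatureMatrix(values, sample_ids, X.feature_ids)
    yraw = meta.loc[keep, outcome]
    if outcome_kind == "continuous":
        y = OutcomeVector(pd.to_numeric(yraw).to_numpy(float), "continuous")
    else:
        y = OutcomeVector(yraw.to_numpy(), "binary")
    Z = None
    if covariates:
        zdf = meta.loc[keep, list(covariates)].apply(pd.to_numeric, errors="raise")
        Z = CovariateTable(zdf.to_numpy(float), list(covariates))
    return Xk, y, Z, n_dropped


def filter_features(X: FeatureMatrix, exclude_ids: Sequence, strict: bool = True):
    """Drop the listed features; returns (FeatureMatrix, n_removed)."""
    exclude = {str(f) for f in exclude_ids}
    unknown = exclude - set(X.feature_ids)
    if unknown and strict:
        raise DataError(f"unknown feature(s) in exclusion list: {sorted(unknown)[:5]}")
    keep = [f for f in X.feature_ids if f not in exclude]
    n_removed = X.n_features - len(keep)
    log.info("filter_features: removed %d feature(s)", n_removed)
    return X.select(keep), n_removed
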