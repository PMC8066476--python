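"""TSV I/O, covariate residualization, and the aberrant-interval transform.

The matrix convention is features x samples: header row of sample ids,
first column of feature ids.  Labels are a two-column TSV
(``sample_id``, ``status``) with status 0 = control, 1 = case; on load the
matrix columns are reordered to the label file's sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .significance import AberrationTestResult
from .walk import Direction

__all__ = [
    "FeatureMatrix",
    "read_matrix",
    "read_labels",
    "align",
    "write_results",
    "residualize_covariates",
    "transform_feature",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Features x samples numeric matrix with string ids."""

    feature_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        object.__setattr__(self, "feature_ids", list(self.feature_ids))
        object.__setattr__(self, "sample_ids", list(self.sample_ids))
        object.__setattr__(self, "values", values)

    @property
    def values_array(self) -> np.ndarray:
        return self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(
            feature_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=np.float64),
        )


def read_matrix(path) -> FeatureMatrix:
    """Load a features x samples TSV, dropping rows with missing cells."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {path}: {dupes[:5]}")
    if frame.columns.duplicated().any():
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes[:5]}")
    try:
        frame = frame.astype(np.float64)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cell in matrix {path}: {err}") from err
    missing = frame.isna().any(axis=1)
    if missing.any():
        logger.warning(
            "dropping %d feature rows with missing values", int(missing.sum())
        )
        frame = frame.loc[~missing]
    return FeatureMatrix.from_frame(frame)


def read_labels(path) -> pd.Series:
    """Load the labels TSV; returns status indexed by sample_id."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "status"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"labels file {path} must have columns sample_id and status"
        )
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids in {path}: {dupes.tolist()[:5]}")
    bad = ~frame["status"].isin([0, 1])
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(
            f"non-binary status in {path} at line(s) {lines[:5]}"
        )
    return pd.Series(
        frame["status"].to_numpy(dtype=np.int8),
        index=frame["sample_id"].tolist(),
        name="status",
    )


def align(matrix: FeatureMatrix, labels: pd.Series) -> tuple[FeatureMatrix, np.ndarray]:
    """Reorder matrix columns to the labels' sample order."""
    missing = [s for s in labels.index if s not in set(matrix.sample_ids)]
    extra = [s for s in matrix.sample_ids if s not in set(labels.index)]
    if missing or extra:
        raise ValueError(
            "sample ids do not match between matrix and labels; "
            f"missing from matrix: {missing[:5]}; unlabeled: {extra[:5]}"
        )
    pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    cols = [pos[s] for s in labels.index]
    reordered = FeatureMatrix(
        feature_ids=matrix.feature_ids,
        sample_ids=list(labels.index),
        values=matrix.values[:, cols],
    )
    return reordered, labels.to_numpy(dtype=np.int8)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def residualize_covariates(matrix: FeatureMatrix, covariates) -> FeatureMatrix:
    """Per-feature OLS residuals against an intercept plus covariates.

    A simple linear fallback for known confounders; hidden-factor removal is
    expected upstream.
    """
    cov = pd.DataFrame(covariates)
    if cov.shape[0] != len(matrix.sample_ids):
        raise ValueError(
            f"covariates have {cov.shape[0]} rows but the matrix has "
            f"{len(matrix.sample_ids)} samples"
        )
    values = cov.to_numpy(dtype=np.float64)
    inert = np.all(values == 0.0, axis=0) if values.size else np.zeros(0, bool)
    if inert.any():
        logger.info(
            "ignoring %d identically-zero covariate column(s)", int(inert.sum())
        )
        cov = cov.loc[:, ~inert]
        values = values[:, ~inert]
    design = np.column_stack([np.ones(cov.shape[0]), values])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns not adding rank, left to right
        collinear = []
        kept = np.ones((design.shape[0], 0))
        for j in range(design.shape[1]):
            cand = np.column_stack([kept, design[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                name = "intercept" if j == 0 else str(cov.columns[j - 1])
                collinear.append(name)
        raise ValueError(f"collinear covariate columns: {collinear}")
    coef, *_ = np.linalg.lstsq(design, matrix.values.T, rcond=None)
    residuals = matrix.values - (design @ coef).T
    return FeatureMatrix(
        feature_ids=matrix.feature_ids,
        sample_ids=matrix.sample_ids,
        values=residuals,
    )


def transform_feature(values, result: AberrationTestResult) -> np.ndarray:
    """Zero out samples outside the aberrant interval.

    Samples beyond ``result.boundary_value`` (inclusive) in the result's
    direction keep their value; all others are set to zero.  Applied before
    classification so models see only the dysregulated range.  Degenerate
    results map everything to zero.
    """
    values = np.asarray(values, dtype=np.float64)
    if result.degenerate:
        return np.zeros_like(values)
    if Direction(result.direction) is Direction.HIGH_IN_CASES:
        keep = values >= result.boundary_value
    else:
        keep = values <= result.boundary_value
    return np.where(keep, values, 0.0)
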