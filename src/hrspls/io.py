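"""Delimited-matrix I/O, sample alignment and column standardization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "read_matrix",
    "write_matrix",
    "align_samples",
    "standardize_columns",
]

logger = logging.getLogger(__name__)


class MatrixFormatError(ValueError):
    """The on-disk matrix violates the format contract."""


@dataclass
class OmicsMatrix:
    """A samples x features block with row/column identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise MatrixFormatError("id lengths do not match matrix shape")
        for label, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = pd.Index(ids).duplicated()
            if dup.any():
                bad = [i for i, d in zip(ids, dup) if d]
                raise MatrixFormatError(f"duplicate {label} id(s): {bad[:5]}")
        if n < 3 or p < 2:
            raise MatrixFormatError(f"matrix too small ({n} samples x {p} features)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


def read_matrix(
    path,
    orientation: str = "samples",
    delimiter: str = "\t",
    missing: str = "error",
    name: str = "",
) -> OmicsMatrix:
    """Read a delimited matrix with a header row and an id column.

    ``orientation`` says what the file's *rows* are: ``"samples"`` (the
    default) or ``"features"``; the result is always samples x features.
    Missing values raise by default; ``missing="impute_mean"`` fills each
    feature with its mean and logs the count.
    """
    try:
        # pandas silently mangles duplicate header names, so check them raw
        header = pd.read_csv(path, sep=delimiter, header=None, nrows=1)
        raw_cols = [str(c) for c in header.iloc[0, 1:]]
        dup_cols = pd.Index(raw_cols)[pd.Index(raw_cols).duplicated()].unique().tolist()
        if dup_cols:
            label = "feature" if orientation == "samples" else "sample"
            raise MatrixFormatError(f"{path}: duplicated {label} id(s): {dup_cols[:5]}")
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise MatrixFormatError(f"{path}: file is empty") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no data rows/columns")
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise MatrixFormatError("orientation must be 'samples' or 'features'")

    for axis, label in ((df.index, "sample"), (df.columns, "feature")):
        dup = axis[axis.duplicated()].unique().tolist()
        if dup:
            raise MatrixFormatError(f"{path}: duplicated {label} id(s): {dup[:5]}")

    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell(s): {exc}") from exc
    nan_mask = np.isnan(values)
    if nan_mask.any():
        if missing == "impute_mean":
            col_mean = np.nanmean(values, axis=0)
            values = np.where(nan_mask, col_mean, values)
            logger.info("%s: imputed %d missing value(s) with feature means", path, nan_mask.sum())
        else:
            raise MatrixFormatError(
                f"{path}: {int(nan_mask.sum())} missing value(s); "
                "set missing='impute_mean' to fill with feature means"
            )
    return OmicsMatrix(
        values=values,
        sample_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        name=name or str(path),
    )


def write_matrix(m: OmicsMatrix, path, delimiter: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=delimiter, index_label="id")


def align_samples(x: OmicsMatrix, y: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Reorder both blocks to their shared samples (X's order); drop the rest."""
    shared = [s for s in x.sample_ids if s in set(y.sample_ids)]
    dropped = (len(x.sample_ids) - len(shared)) + (len(y.sample_ids) - len(shared))
    if dropped:
        logger.warning("dropped %d unmatched sample(s) during alignment", dropped)
    if len(shared) < 3:
        raise MatrixFormatError("fewer than 3 shared samples between the two blocks")
    xi = [x.sample_ids.index(s) for s in shared]
    yi = [y.sample_ids.index(s) for s in shared]
    return (
        OmicsMatrix(x.values[xi], shared, x.feature_ids, x.name),
        OmicsMatrix(y.values[yi], shared, y.feature_ids, y.name),
    )


def standardize_columns(values: np.ndarray, drop_constant: bool = True):
    """Z-score each column (population sd); returns (Z, kept_indices).

    Constant columns carry no signal and break both the Z-score membership
    rule and profile distances, so they are dropped with a warning by
    default (or left centered when ``drop_constant=False``).
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    constant = sd == 0
    kept = np.flatnonzero(~constant) if drop_constant else np.arange(values.shape[1])
    if constant.any():
        logger.warning("%d constant column(s) %s", constant.sum(),
                       "dropped" if drop_constant else "centered only")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    return z[:, kept], kept
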