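"""Core data containers, delimited-matrix I/O and column standardization.

A :class:`FeatureMatrix` is a samples x features numeric block with row
(sample) and column (feature) names. A :class:`DataBlock` bundles one
"imaging" block ``X`` with ``M`` "genetic" blocks ``Y[m]`` sharing the same
samples, plus an optional binary label vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "FeatureMatrix",
    "DataBlock",
    "read_matrix",
    "write_matrix",
    "standardize",
    "standardize_block",
    "assemble_block",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Numeric n x d block with sample and feature names.

    Attributes
    ----------
    values : ndarray of shape (n, d)
        Dense float matrix; all entries finite.
    sample_ids : tuple of str
        Row names, unique, length n.
    feature_names : tuple of str
        Column names, unique, length d.
    standardized : bool
        True once columns have been centered/scaled by :func:`standardize`.
    """

    values: np.ndarray
    sample_ids: tuple
    feature_names: tuple
    standardized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite entry at row {i} ({self.sample_ids[i]!r}), "
                f"column {j} ({self.feature_names[j]!r})"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(s) for s in self.feature_names))
        n, d = values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != d:
            raise ValidationError(f"{len(self.feature_names)} feature names for {d} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_names)) != d:
            dupes = sorted({x for x in self.feature_names if self.feature_names.count(x) > 1})
            raise ValidationError(f"duplicate feature names: {dupes}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids),
                          columns=list(self.feature_names))
        df.index.name = "sample_id"
        return df


@dataclass(frozen=True)
class DataBlock:
    """One X block plus M Y blocks over identical, identically ordered samples."""

    X: FeatureMatrix
    Y: tuple
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "Y", tuple(self.Y))
        if len(self.Y) == 0:
            raise ValidationError("DataBlock requires at least one Y block")
        ids = self.X.sample_ids
        for m, y in enumerate(self.Y):
            if y.sample_ids != ids:
                raise ValidationError(f"Y[{m}] sample ids differ from X")
        qs = {y.n_features for y in self.Y}
        if len(qs) > 1:
            raise ValidationError(
                f"all Y blocks must share one feature count, got {sorted(qs)}"
            )
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape != (self.X.n_samples,):
                raise ValidationError(
                    f"labels length {labels.shape} does not match n={self.X.n_samples}"
                )
            uniq = set(np.unique(labels).tolist())
            if not uniq <= {0, 1}:
                raise ValidationError(f"labels must be binary 0/1, got values {sorted(uniq)}")
            object.__setattr__(self, "labels", labels.astype(int))

    @property
    def M(self) -> int:
        return len(self.Y)

    @property
    def n_samples(self) -> int:
        return self.X.n_samples

    @property
    def standardized(self) -> bool:
        return self.X.standardized and all(y.standardized for y in self.Y)

    def subset(self, indices: Sequence[int]) -> "DataBlock":
        """Row subset (e.g. a train/test split), preserving given order."""
        idx = np.asarray(indices, dtype=int)
        take = lambda fm: FeatureMatrix(
            fm.values[idx], [fm.sample_ids[i] for i in idx],
            fm.feature_names, fm.standardized,
        )
        labels = None if self.labels is None else self.labels[idx]
        return DataBlock(take(self.X), tuple(take(y) for y in self.Y), labels)


def read_matrix(path, delimiter: str = ",") -> FeatureMatrix:
    """Read a delimited matrix: header of feature names, first column sample ids.

    Rejects missing and non-numeric cells, naming the offending coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[i, j]
        kind = "missing value" if pd.isna(raw) else f"non-numeric cell {raw!r}"
        raise ValidationError(
            f"{kind} at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    return FeatureMatrix(numeric.to_numpy(dtype=float),
                         list(df.index.astype(str)), list(df.columns.astype(str)))


def write_matrix(m: FeatureMatrix, path, delimiter: str = ",") -> None:
    """Write a FeatureMatrix as delimited text (header row, sample_id column)."""
    m.to_frame().to_csv(path, sep=delimiter)


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Center every column to mean 0 and scale non-constant columns to unit sd.

    Uses the sample (n-1 denominator) standard deviation. Constant columns are
    centered to zero and left unscaled. Idempotent.
    """
    if m.n_samples < 2:
        raise ValidationError(f"standardize requires n >= 2, got n={m.n_samples}")
    vals = m.values - m.values.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    nz = sd > 0
    vals[:, nz] /= sd[nz]
    return FeatureMatrix(vals, m.sample_ids, m.feature_names, standardized=True)


def standardize_block(block: DataBlock) -> DataBlock:
    """Standardize X and every Y block; labels pass through unchanged."""
    return DataBlock(standardize(block.X),
                     tuple(standardize(y) for y in block.Y), block.labels)


def assemble_block(X: FeatureMatrix, Ys: Sequence[FeatureMatrix],
                   labels=None) -> DataBlock:
    """Align blocks by sample-id intersection (X order) and bundle them.

    ``labels``, if given, must be aligned with X's original sample order and
    is subset along with the rows.
    """
    Ys = list(Ys)
    common = set(X.sample_ids)
    for y in Ys:
        common &= set(y.sample_ids)
    if not common:
        raise ValidationError("empty sample-id intersection between blocks")
    keep = [i for i, s in enumerate(X.sample_ids) if s in common]
    order = [X.sample_ids[i] for i in keep]

    def reindex(fm: FeatureMatrix) -> FeatureMatrix:
        pos = {s: i for i, s in enumerate(fm.sample_ids)}
        idx = [pos[s] for s in order]
        return FeatureMatrix(fm.values[idx], order, fm.feature_names, fm.standardized)

    qs = sorted({y.n_features for y in Ys})
    if len(qs) > 1:
        raise ValidationError(f"Y blocks must share a feature count, got {qs}")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (X.n_samples,):
            raise ValidationError(
                f"labels length {labels.shape[0] if labels.ndim else '?'} "
                f"does not match X's {X.n_samples} samples"
            )
        labels = labels[keep]
    return DataBlock(reindex(X), tuple(reindex(y) for y in Ys), labels)
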