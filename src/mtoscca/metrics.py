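"""Canonical correlation metrics, hyperparameter grid search and splitters."""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import DataBlock
from .exceptions import NumericalError, ValidationError
from .solvers import Hyperparams, fit_mtoscca, fit_mtscca

__all__ = [
    "GridSpec",
    "GridResult",
    "pearson",
    "ccc",
    "abs_ccc",
    "grid_search",
    "train_test_split",
    "kfold_indices",
]

logger = logging.getLogger(__name__)

#: the four-point candidate list used by the reference grid-search protocol
DEFAULT_CANDIDATES = (0.001, 0.01, 0.1, 1.0)

_SOLVERS = {"mtoscca": fit_mtoscca, "mtscca": fit_mtscca}


@dataclass(frozen=True)
class GridSpec:
    """Candidate lists for the five penalty parameters."""

    lambda_v1: tuple = DEFAULT_CANDIDATES
    lambda_v2: tuple = DEFAULT_CANDIDATES
    lambda_v3: tuple = DEFAULT_CANDIDATES
    lambda_u1: tuple = DEFAULT_CANDIDATES
    lambda_u2: tuple = DEFAULT_CANDIDATES

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            cand = tuple(float(c) for c in getattr(self, name))
            if len(cand) == 0:
                raise ValidationError(f"{name} candidate list is empty")
            if any(c < 0 for c in cand):
                raise ValidationError(f"{name} candidates must be >= 0, got {cand}")
            object.__setattr__(self, name, cand)

    def combinations(self) -> List[tuple]:
        """Cartesian product, lexicographic: lambda_v1 slowest, lambda_u2 fastest."""
        return list(itertools.product(self.lambda_v1, self.lambda_v2,
                                      self.lambda_v3, self.lambda_u1,
                                      self.lambda_u2))

    @property
    def n_combinations(self) -> int:
        return (len(self.lambda_v1) * len(self.lambda_v2) * len(self.lambda_v3)
                * len(self.lambda_u1) * len(self.lambda_u2))


@dataclass(frozen=True)
class GridResult:
    """One row per combination with per-task |CCC| and their mean."""

    table: pd.DataFrame
    best_index: Optional[int]

    @property
    def best_row(self) -> pd.Series:
        if self.best_index is None:
            raise ValidationError("no non-diverged grid row available")
        return self.table.loc[self.best_index]


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation; rejects constant or too-short inputs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("pearson requires n >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValidationError("correlation undefined for a constant input")
    return float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))


def ccc(X: np.ndarray, u: np.ndarray, Y_m: np.ndarray, v_m: np.ndarray) -> float:
    """Canonical correlation coefficient: Pearson correlation of X@u and Y@v."""
    return pearson(np.asarray(X) @ np.asarray(u), np.asarray(Y_m) @ np.asarray(v_m))


def abs_ccc(X, u, Y_m, v_m) -> float:
    return abs(ccc(X, u, Y_m, v_m))


def grid_search(block: DataBlock, grid: GridSpec = GridSpec(),
                solver: str = "mtoscca", seed: int = 0,
                hp_base: Optional[Hyperparams] = None,
                init: str = "ones") -> GridResult:
    """Exhaustive grid search maximizing the mean |CCC| over tasks.

    Enumerates the Cartesian product in fixed lexicographic order
    (``lambda_v1`` slowest, ``lambda_u2`` fastest) so that "the k-th
    combination" is reproducible. Evaluates in-sample on the given block.
    Diverging fits are recorded with ``diverged=True`` and excluded from the
    argmax; ties break toward the lowest row index.
    """
    if solver not in _SOLVERS:
        raise ValidationError(f"solver must be one of {sorted(_SOLVERS)}, got {solver!r}")
    fit = _SOLVERS[solver]
    base = hp_base if hp_base is not None else Hyperparams()
    base = replace(base, seed=seed)
    M = block.M
    rows = []
    for combo in grid.combinations():
        lv1, lv2, lv3, lu1, lu2 = combo
        hp = replace(base, lambda_v1=lv1, lambda_v2=lv2, lambda_v3=lv3,
                     lambda_u1=lu1, lambda_u2=lu2)
        row = dict(lambda_v1=lv1, lambda_v2=lv2, lambda_v3=lv3,
                   lambda_u1=lu1, lambda_u2=lu2)
        try:
            res = fit(block, hp, init=init)
            abscc = np.abs(res.ccc)
            for m in range(M):
                row[f"ccc{m + 1}_abs"] = abscc[m]
            row["ccc_mean"] = float(abscc.mean())
            row["diverged"] = False
        except NumericalError as exc:
            logger.warning("grid point %s diverged: %s", combo, exc)
            warnings.warn(f"grid point {combo} diverged: {exc}", RuntimeWarning,
                          stacklevel=2)
            for m in range(M):
                row[f"ccc{m + 1}_abs"] = np.nan
            row["ccc_mean"] = np.nan
            row["diverged"] = True
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.loc[~table["diverged"], "ccc_mean"]
    best = int(ok.idxmax()) if len(ok) else None
    return GridResult(table, best)


def train_test_split(labels: Sequence[int], test_fraction: float, seed: int = 0,
                     stratified: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Random train/test partition of ``range(len(labels))``.

    The total test count is ``round(n * test_fraction)`` (round-half-even);
    with ``stratified=True``, per-class counts are the rounded class shares
    adjusted (by largest fractional remainder) so they sum to the total.
    Returns sorted (train, test) index arrays.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = int(round(n * test_fraction))
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
    else:
        classes = np.unique(labels)
        exact = {c: (labels == c).sum() * test_fraction for c in classes}
        counts = {c: int(round(exact[c])) for c in classes}
        # repair rounding so the class counts sum to the overall test count
        remainders = sorted(classes, key=lambda c: (-(exact[c] - np.floor(exact[c])), c))
        i = 0
        while sum(counts.values()) < n_test:
            counts[remainders[i % len(classes)]] += 1
            i += 1
        i = 0
        while sum(counts.values()) > n_test:
            counts[remainders[-1 - (i % len(classes))]] -= 1
            i += 1
        test_parts = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            if counts[c] > idx.size or counts[c] < 0:
                raise ValidationError(
                    f"class {c} has {idx.size} samples but needs {counts[c]} in the test set"
                )
            test_parts.append(rng.permutation(idx)[:counts[c]])
        test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def kfold_indices(n: int, k: int, seed: int = 0) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition: k (train, validation) index pairs.

    Fold sizes differ by at most one; every index lands in exactly one
    validation fold.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValidationError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i, val in enumerate(folds):
        train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != i]))
        out.append((train, np.sort(val)))
    return out
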