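"""Biomarker evaluation: feature screening, top-k weights, ROC/AUC with CIs.

The pieces here mirror a typical imaging-genetics discovery workflow: a
random-forest screen to equalize block widths before the solver sees the
data, extraction of the highest-|weight| features per modality from a fitted
model, and diagnostic evaluation of single and combined features on a
held-out test split (AUC with DeLong or stratified-bootstrap confidence
intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data import DataBlock, FeatureMatrix
from .exceptions import ValidationError
from .metrics import kfold_indices, train_test_split
from .solvers import Hyperparams, WeightSet, fit_mtoscca, fit_mtscca

__all__ = [
    "EvalReport",
    "rf_screen",
    "top_features",
    "roc_auc",
    "auc_ci",
    "combined_auc",
    "selection_frequency",
    "run_evaluation",
]

logger = logging.getLogger(__name__)

_SOLVERS = {"mtoscca": fit_mtoscca, "mtscca": fit_mtscca}

#: small default RF tuning grid; exhaustive but cheap
DEFAULT_RF_GRID = {"n_estimators": [100, 200], "max_depth": [None, 4]}


@dataclass(frozen=True)
class EvalReport:
    """Per-feature and combined-feature AUC rows plus run metadata."""

    per_feature: pd.DataFrame  # columns: predictive_variable, modality, auc, ci_low, ci_high
    combined: pd.DataFrame     # columns: predictive_variable, n_features, auc, ci_low, ci_high
    top: pd.DataFrame          # columns: modality, rank, feature, weight
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        for df in (self.per_feature, self.combined):
            if len(df):
                if not ((df["auc"] >= 0) & (df["auc"] <= 1)).all():
                    raise ValidationError("AUC outside [0, 1]")
                if not ((df["ci_low"] <= df["auc"] + 1e-12)
                        & (df["auc"] <= df["ci_high"] + 1e-12)).all():
                    raise ValidationError("confidence interval does not bracket the AUC")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    uniq = set(np.unique(labels).tolist())
    if uniq != {0, 1}:
        raise ValidationError(f"need both classes present (0 and 1), got {sorted(uniq)}")
    return labels


def rf_screen(features: FeatureMatrix, labels: Sequence[int], n_keep: int,
              seed: int = 0, param_grid: Optional[dict] = None,
              cv: int = 3, importance: str = "impurity") -> np.ndarray:
    """Rank features by random-forest importance and keep the top ``n_keep``.

    A forest is tuned by exhaustive grid search with stratified CV, then the
    features are ordered by importance (descending, ties by original column
    order). Intended to be run on training data only to avoid leakage.
    """
    labels = _check_binary(np.asarray(labels))
    if labels.shape[0] != features.n_samples:
        raise ValidationError(
            f"labels length {labels.shape[0]} != n samples {features.n_samples}")
    if not 0 < n_keep <= features.n_features:
        raise ValidationError(
            f"n_keep must be in [1, {features.n_features}], got {n_keep}")
    if importance not in ("impurity", "permutation"):
        raise ValidationError(f"importance must be 'impurity' or 'permutation', got {importance!r}")
    grid = param_grid if param_grid is not None else DEFAULT_RF_GRID
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid,
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        scoring="roc_auc",
    )
    search.fit(features.values, labels)
    forest = search.best_estimator_
    if importance == "impurity":
        imp = forest.feature_importances_
    else:
        from sklearn.inspection import permutation_importance
        imp = permutation_importance(forest, features.values, labels,
                                     random_state=seed).importances_mean
    order = np.argsort(-imp, kind="stable")
    return order[:n_keep]


def top_features(weights: WeightSet, names: Sequence[Sequence[str]],
                 k: int) -> pd.DataFrame:
    """Top-k features per modality ranked by |weight|.

    ``names`` lists feature names per modality: the X block first, then one
    list per Y block. X-block features are scored by the mean of their weight
    across task columns of U (a single consensus weight per feature); the
    m-th Y block uses column m of V. Ties break toward the original feature
    order; weights are reported signed.
    """
    if k < 0:
        raise ValidationError(f"k must be >= 0, got {k}")
    M = weights.M
    if len(names) != M + 1:
        raise ValidationError(f"expected {M + 1} name lists (X plus {M} Y blocks), got {len(names)}")
    columns = [("X", np.asarray(weights.U).mean(axis=1))]
    for m in range(M):
        columns.append((f"Y{m + 1}", np.asarray(weights.V)[:, m]))
    rows = []
    for (modality, w), block_names in zip(columns, names):
        block_names = list(block_names)
        if len(block_names) != w.size:
            raise ValidationError(
                f"{modality}: {len(block_names)} names for {w.size} weights")
        if k > w.size:
            raise ValidationError(f"k={k} exceeds {modality}'s {w.size} features")
        order = np.argsort(-np.abs(w), kind="stable")[:k]
        for rank, j in enumerate(order, start=1):
            rows.append((modality, rank, block_names[j], float(w[j])))
    return pd.DataFrame(rows, columns=["modality", "rank", "feature", "weight"])


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValidationError(f"shape mismatch: {scores.shape} vs {labels.shape}")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores contain non-finite values")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _delong_ci(scores: np.ndarray, labels: np.ndarray,
               level: float = 0.95) -> Tuple[float, float]:
    """DeLong normal-approximation CI via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    v10 = (all_ranks[:m] - rankdata(pos)) / n           # placements of cases
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m     # placements of controls
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def auc_ci(scores: Sequence[float], labels: Sequence[int],
           method: str = "delong", n_boot: int = 2000,
           seed: int = 0) -> Tuple[float, float]:
    """95% confidence interval for the AUC, clipped to [0, 1].

    ``method='delong'`` (default) is deterministic; ``method='bootstrap'``
    resamples cases and controls separately (stratified percentile interval),
    so resamples can never collapse to a single class.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_binary(labels)
    if method == "delong":
        return _delong_ci(scores, labels)
    if method != "bootstrap":
        raise ValidationError(f"method must be 'delong' or 'bootstrap', got {method!r}")
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    stats = np.empty(n_boot)
    boot_labels = np.concatenate([np.ones(pos.size, dtype=int),
                                  np.zeros(neg.size, dtype=int)])
    for b in range(n_boot):
        sample = np.concatenate([rng.choice(pos, size=pos.size, replace=True),
                                 rng.choice(neg, size=neg.size, replace=True)])
        stats[b] = roc_auc(sample, boot_labels)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _extract_features(block: DataBlock, pairs: Sequence[Tuple[str, str]]) -> np.ndarray:
    cols = []
    lookup = {"X": block.X}
    for m, y in enumerate(block.Y):
        lookup[f"Y{m + 1}"] = y
    for modality, feature in pairs:
        if modality not in lookup:
            raise ValidationError(f"unknown modality {modality!r}; choose from {sorted(lookup)}")
        fm = lookup[modality]
        try:
            j = fm.feature_names.index(feature)
        except ValueError:
            raise ValidationError(f"feature {feature!r} not found in block {modality}")
        cols.append(fm.values[:, j])
    return np.column_stack(cols)


def combined_auc(train_block: DataBlock, test_block: DataBlock,
                 feature_sets: Dict[str, Sequence[Tuple[str, str]]],
                 seed: int = 0, ci_method: str = "delong",
                 n_boot: int = 2000) -> pd.DataFrame:
    """Joint predictive performance of named feature panels.

    For each named set of (modality, feature) pairs a ridge-penalized
    logistic model is fitted on the training split and scored on the test
    split; rows report test AUC with a 95% CI.
    """
    if train_block.labels is None or test_block.labels is None:
        raise ValidationError("both blocks need labels for combined evaluation")
    y_train = _check_binary(train_block.labels)
    y_test = _check_binary(test_block.labels)
    rows = []
    for name, pairs in feature_sets.items():
        pairs = list(pairs)
        if not pairs:
            raise ValidationError(f"feature set {name!r} is empty")
        Ftr = _extract_features(train_block, pairs)
        Fte = _extract_features(test_block, pairs)
        model = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=1000, random_state=seed),
        )
        model.fit(Ftr, y_train)
        scores = model.predict_proba(Fte)[:, 1]
        auc = roc_auc(scores, y_test)
        lo, hi = auc_ci(scores, y_test, method=ci_method, n_boot=n_boot, seed=seed)
        rows.append((name, len(pairs), auc, lo, hi))
    return pd.DataFrame(rows, columns=["predictive_variable", "n_features",
                                       "auc", "ci_low", "ci_high"])


def selection_frequency(block: DataBlock, hp: Hyperparams, k: int = 10,
                        n_folds: int = 5, seed: int = 0,
                        solver: str = "mtoscca") -> pd.DataFrame:
    """k-fold stability harness: how often each feature makes the top-k.

    Refits the solver on each fold's training portion and tallies, per
    modality, the fraction of folds in which each feature appears among the
    top-k. Reports only features selected at least once.
    """
    if solver not in _SOLVERS:
        raise ValidationError(f"unknown solver {solver!r}")
    names = [list(block.X.feature_names)] + [list(y.feature_names) for y in block.Y]
    counts: Dict[Tuple[str, str], int] = {}
    folds = kfold_indices(block.n_samples, n_folds, seed)
    for train_idx, _ in folds:
        res = _SOLVERS[solver](block.subset(train_idx), hp)
        top = top_features(res.weights, names, k)
        for _, row in top.iterrows():
            key = (row["modality"], row["feature"])
            counts[key] = counts.get(key, 0) + 1
    rows = [(mod, feat, cnt / n_folds) for (mod, feat), cnt in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["modality", "feature", "frequency"])


def _modality_combinations(modalities: Sequence[str]) -> List[Tuple[str, ...]]:
    """All non-empty subsets, singletons first, preserving modality order."""
    out: List[Tuple[str, ...]] = []
    n = len(modalities)
    for size in range(1, n + 1):
        import itertools
        out.extend(itertools.combinations(modalities, size))
    return out


def _align(X: FeatureMatrix, Ys: Sequence[FeatureMatrix], labels):
    """Sample-id intersection alignment (X order) without the equal-q check."""
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

    labels = np.asarray(labels)
    if labels.shape != (X.n_samples,):
        raise ValidationError(
            f"labels length does not match X's {X.n_samples} samples")
    return reindex(X), [reindex(y) for y in Ys], labels[keep]


def run_evaluation(X: FeatureMatrix, Ys: Sequence[FeatureMatrix], labels,
                   hp: Hyperparams = Hyperparams(),
                   k: int = 10, test_fraction: float = 0.2, seed: int = 0,
                   solver: str = "mtoscca", ci_method: str = "delong",
                   n_boot: int = 2000, stratified: bool = True,
                   screen_to: Optional[int] = None) -> EvalReport:
    """End-to-end evaluation: split, screen, fit, rank, score feature panels.

    The solver is fitted on the training split only; per-feature AUCs use the
    raw held-out feature values as scores (reported as-is, no direction
    flipping), and combined panels use a ridge-logistic combiner trained on
    the training split.

    If ``screen_to`` is given (or the Y blocks have unequal widths, in which
    case the narrowest width is used), every wider Y block is reduced to that
    many columns by :func:`rf_screen` run on the training rows only.
    """
    if labels is None:
        raise ValidationError("evaluation requires labels")
    if solver not in _SOLVERS:
        raise ValidationError(f"unknown solver {solver!r}")
    X, Ys, labels = _align(X, list(Ys), labels)
    train_idx, test_idx = train_test_split(labels, test_fraction, seed,
                                           stratified=stratified)

    widths = {y.n_features for y in Ys}
    if screen_to is None and len(widths) > 1:
        screen_to = min(widths)
    if screen_to is not None:
        screened = []
        for y in Ys:
            if y.n_features > screen_to:
                train_y = FeatureMatrix(y.values[train_idx],
                                        [y.sample_ids[i] for i in train_idx],
                                        y.feature_names, y.standardized)
                keep = np.sort(rf_screen(train_y, labels[train_idx],
                                         screen_to, seed=seed))
                y = FeatureMatrix(y.values[:, keep], y.sample_ids,
                                  [y.feature_names[j] for j in keep],
                                  y.standardized)
            screened.append(y)
        Ys = screened

    block = DataBlock(X, tuple(Ys), labels)
    train_block = block.subset(train_idx)
    test_block = block.subset(test_idx)

    res = _SOLVERS[solver](train_block, hp)
    names = [list(block.X.feature_names)] + [list(y.feature_names) for y in block.Y]
    top = top_features(res.weights, names, k)

    y_test = test_block.labels
    feature_rows = []
    for _, row in top.iterrows():
        scores = _extract_features(test_block, [(row["modality"], row["feature"])]).ravel()
        auc = roc_auc(scores, y_test)
        lo, hi = auc_ci(scores, y_test, method=ci_method, n_boot=n_boot, seed=seed)
        feature_rows.append((row["feature"], row["modality"], auc, lo, hi))
    per_feature = pd.DataFrame(
        feature_rows,
        columns=["predictive_variable", "modality", "auc", "ci_low", "ci_high"])

    modalities = ["X"] + [f"Y{m + 1}" for m in range(block.M)]
    panels: Dict[str, List[Tuple[str, str]]] = {}
    for combo in _modality_combinations(modalities):
        label = " + ".join(f"top {k} {mod}" for mod in combo)
        pairs = [(row["modality"], row["feature"])
                 for _, row in top.iterrows() if row["modality"] in combo]
        if pairs:
            panels[label] = pairs
    combined = combined_auc(train_block, test_block, panels, seed=seed,
                            ci_method=ci_method, n_boot=n_boot)

    metadata = dict(seed=seed, solver=solver, k=k, test_fraction=test_fraction,
                    ci_method=ci_method, n_boot=n_boot,
                    n_train=len(train_idx), n_test=len(test_idx),
                    converged=bool(res.converged), n_iter=int(res.n_iter),
                    ccc=[float(c) for c in res.ccc])
    return EvalReport(per_feature, combined, top, metadata)
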