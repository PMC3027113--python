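"""Random-forest training, tuning, evaluation and feature importance.

The classification protocol: a grid search over the forest size (``ntree``)
and the number of features tried per split (``mtry``), scored by pooled
out-of-fold Matthews correlation coefficient (MCC) under stratified 5-fold
cross-validation; permutation importance measured as the mean decrease in
out-of-bag accuracy when one feature is shuffled, repeated (default 100
times) and averaged. Disease is the positive class.

Evaluation metrics:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FN + TN + FP)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP))

with MCC defined as 0 when any factor of the denominator is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                      _get_n_samples_bootstrap)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

POSITIVE_LABEL = "disease"
NEGATIVE_LABEL = "polymorphism"

FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised for invalid training/prediction input."""


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the derived evaluation measures (fractions)."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    def as_dict(self, percent: bool = True) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "accuracy": self.accuracy * scale,
            "mcc": self.mcc,
        }


def metrics(tp: int, tn: int, fp: int, fn: int) -> EvalMetrics:
    """Evaluation measures from confusion counts; MCC 0/0 convention -> 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ModelError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ModelError("empty confusion matrix")
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total
    denom = (tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                       specificity=spec, accuracy=acc, mcc=mcc)


def metrics_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """Confusion-count metrics with ``disease`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    return metrics(tp=int(np.sum(pos & pred_pos)),
                   tn=int(np.sum(~pos & ~pred_pos)),
                   fp=int(np.sum(~pos & pred_pos)),
                   fn=int(np.sum(pos & ~pred_pos)))


@dataclass
class TuneGrid:
    """Grid-search space for the forest hyperparameters."""

    ntree_values: tuple[int, ...] = (100, 200, 300, 400, 500)
    mtry_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ntree_values or not self.mtry_values:
            raise ModelError("grid must be non-empty")
        if self.folds < 2:
            raise ModelError("need at least 2 folds")


@dataclass
class CVResult:
    """Outcome of the grid-searched cross-validation."""

    best_ntree: int
    best_mtry: int
    fold_metrics: list[EvalMetrics]
    pooled: EvalMetrics
    grid_scores: pd.DataFrame = field(repr=False, default=None)


def _make_forest(ntree: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, oob_score=False,
        random_state=seed, n_jobs=1,
    )


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = set(np.unique(y))
    if not classes <= {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ModelError(f"labels must be {POSITIVE_LABEL!r}/{NEGATIVE_LABEL!r}, "
                         f"got {sorted(classes)}")
    if len(classes) < 2:
        raise ModelError("need both classes present")
    return y


def cross_validate(features: pd.DataFrame, labels, grid: TuneGrid | None = None,
                   groups=None) -> CVResult:
    """Grid search over (ntree, mtry) scored by pooled out-of-fold MCC.

    Folds are stratified by class; when ``groups`` (e.g. protein ids) is
    given, records of one group are kept in the same fold to avoid
    protein-level leakage. Ties in MCC are broken toward fewer trees, then
    smaller mtry. Returns per-fold and pooled metrics at the best grid point.
    """
    grid = grid or TuneGrid()
    y = _check_labels(labels)
    X = features.to_numpy(dtype=float)
    n = len(y)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=grid.folds, shuffle=True,
                                        random_state=grid.seed)
        splits = list(splitter.split(X, y, groups=np.asarray(groups)))
    else:
        splitter = StratifiedKFold(n_splits=grid.folds, shuffle=True,
                                   random_state=grid.seed)
        splits = list(splitter.split(X, y))

    rows = []
    best = None
    for ntree in grid.ntree_values:
        for mtry in grid.mtry_values:
            if mtry > X.shape[1]:
                continue
            pooled_pred = np.empty(n, dtype=object)
            fold_mets = []
            for train_idx, test_idx in splits:
                forest = _make_forest(ntree, mtry, grid.seed)
                forest.fit(X[train_idx], y[train_idx])
                pred = forest.predict(X[test_idx])
                pooled_pred[test_idx] = pred
                fold_mets.append(metrics_from_labels(y[test_idx], pred))
            pooled = metrics_from_labels(y, pooled_pred.astype(str))
            rows.append({"ntree": ntree, "mtry": mtry,
                         "mcc": pooled.mcc, "accuracy": pooled.accuracy})
            cand = (pooled.mcc, -ntree, -mtry, fold_mets, pooled, ntree, mtry)
            if best is None or cand[:3] > best[:3]:
                best = cand
    _, _, _, fold_mets, pooled, ntree, mtry = best
    return CVResult(best_ntree=ntree, best_mtry=mtry, fold_metrics=fold_mets,
                    pooled=pooled, grid_scores=pd.DataFrame(rows))


@dataclass
class TrainedModel:
    """A fitted forest plus the feature schema it expects."""

    forest: RandomForestClassifier
    schema: tuple[str, ...]
    version: int = FORMAT_VERSION


def train(features: pd.DataFrame, labels, ntree: int = 200, mtry: int = 2,
          seed: int = 0) -> TrainedModel:
    """Fit a random forest on the full feature table."""
    y = _check_labels(labels)
    forest = _make_forest(ntree, mtry, seed)
    forest.fit(features.to_numpy(dtype=float), y)
    return TrainedModel(forest=forest, schema=tuple(features.columns))


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-record predicted class and positive-class vote fraction.

    The feature schema is checked by name; missing or extra columns are a
    hard error.
    """
    missing = [c for c in model.schema if c not in features.columns]
    extra = [c for c in features.columns if c not in model.schema]
    if missing or extra:
        raise ModelError(f"feature schema mismatch: missing={missing}, extra={extra}")
    X = features[list(model.schema)].to_numpy(dtype=float)
    proba = model.forest.predict_proba(X)
    pos_col = list(model.forest.classes_).index(POSITIVE_LABEL)
    score = proba[:, pos_col]
    pred = np.where(score >= 0.5, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame({"prediction": pred, "score": score}, index=features.index)


def permutation_importance(model: TrainedModel, features: pd.DataFrame,
                           labels, reps: int = 100, seed: int = 0) -> pd.Series:
    """Out-of-bag permutation importance, averaged over ``reps`` repetitions.

    For each tree, the accuracy on its out-of-bag samples is compared with the
    accuracy after shuffling one feature column; the per-tree drops are
    averaged over trees and repetitions (fresh permutations each repetition).
    Returned sorted descending; ties keep schema order.
    """
    if reps < 1:
        raise ModelError("reps must be >= 1")
    X = features[list(model.schema)].to_numpy(dtype=float)
    forest = model.forest
    # individual trees predict encoded class indices; compare in that space
    class_index = {c: k for k, c in enumerate(forest.classes_)}
    y = np.array([class_index[v] for v in np.asarray(labels)], dtype=float)
    n = len(y)
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    oob_sets = []
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        if oob.size:
            oob_sets.append((tree, oob))

    n_feat = X.shape[1]
    totals = np.zeros(n_feat)
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        rep_rng = np.random.default_rng(rng.integers(0, 2**31))
        drops = np.zeros(n_feat)
        for tree, oob in oob_sets:
            X_oob = X[oob]
            y_oob = y[oob]
            base = np.mean(tree.predict(X_oob) == y_oob)
            for f in range(n_feat):
                saved = X_oob[:, f].copy()
                X_oob[:, f] = saved[rep_rng.permutation(len(saved))]
                drops[f] += base - np.mean(tree.predict(X_oob) == y_oob)
                X_oob[:, f] = saved
        totals += drops / len(oob_sets)
    imp = pd.Series(totals / reps, index=list(model.schema))
    order = np.lexsort((np.arange(len(imp)), -imp.to_numpy()))
    return imp.iloc[order]


def select_top_k(importances: pd.Series, k: int) -> list[str]:
    """Names of the k most important features; ties broken by schema order.

    ``importances`` is as returned by :func:`permutation_importance` (already
    schema-tie-broken); any unsorted Series is re-sorted the same way.
    """
    if k > len(importances):
        raise ModelError(f"k={k} exceeds feature count {len(importances)}")
    order = np.lexsort((np.arange(len(importances)), -importances.to_numpy()))
    return list(importances.iloc[order].index[:k])


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"forest": model.forest, "schema": model.schema,
                 "version": model.version}, path)


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("version") != FORMAT_VERSION:
        raise ModelError(f"unsupported model file version {blob.get('version')}")
    return TrainedModel(forest=blob["forest"], schema=tuple(blob["schema"]),
                        version=blob["version"])
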