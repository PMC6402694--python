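"""Endpoint decoding from delay activity and the geometry of its errors.

Targets are classified with one-vs-one RBF-kernel support vector machines
under stratified k-fold cross validation; errors are summarized as angular
error (minimal circular difference between true and predicted target
angles), arc-length error (angle x ring radius, a cm-scale measure that is
comparable across ring distances), or distance error (|true - predicted|
target distance).  The spatial-plane ablation removes the speed axis (and
every other non-plane dimension) before classification.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core_io import rate_matrix, target_distances
from .subspace import SubspaceModel
from .synthetic import TargetLayout


class StratificationError(ValueError):
    """A class has too few trials for the requested fold count."""


@dataclasses.dataclass
class DecodeResult:
    """Out-of-fold predictions from cross-validated classification."""

    y_true: np.ndarray
    y_pred: np.ndarray
    fold: np.ndarray
    classes: np.ndarray
    confusion: np.ndarray  # rows = true class, in `classes` order
    fold_accuracies: np.ndarray
    accuracy: float
    sem: float  # standard error of the mean accuracy across folds


def _make_svm(grid_search: bool, seed: int):
    svm = SVC(kernel="rbf", C=1.0, gamma="scale")
    if grid_search:
        grid = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.001]}
        return GridSearchCV(svm, grid, cv=3)
    return svm


def crossval_classify(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    grid_search: bool = False,
) -> DecodeResult:
    """Stratified k-fold, one-vs-one RBF-SVM classification.

    Every trial receives an out-of-fold prediction; accuracy is the mean of
    per-fold accuracies with its SEM across folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        bad = classes[np.argmin(counts)]
        raise StratificationError(
            f"class {bad!r} has {counts.min()} trials, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_idx = np.empty(len(y), dtype=int)
    fold_acc = []
    for f, (train, test) in enumerate(skf.split(X, y)):
        clf = _make_svm(grid_search, seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        y_pred[test] = pred
        fold_idx[test] = f
        fold_acc.append(float(np.mean(pred == y[test])))
    fold_acc = np.array(fold_acc)
    conf = confusion_matrix(y, y_pred, labels=classes)
    return DecodeResult(
        y_true=y,
        y_pred=y_pred,
        fold=fold_idx,
        classes=classes,
        confusion=conf,
        fold_accuracies=fold_acc,
        accuracy=float(fold_acc.mean()),
        sem=float(fold_acc.std(ddof=1) / np.sqrt(folds)),
    )


@dataclasses.dataclass
class ErrorDistribution:
    """Per-trial decoding errors under one metric."""

    metric: str  # angle (rad) | arc (cm) | distance (cm)
    errors: np.ndarray
    mean: float
    restricted_mean: Optional[float] = None  # arc only
    restricted_max: Optional[float] = None  # half-circumference of smallest ring


def _condition_positions(layout: TargetLayout) -> dict[int, np.ndarray]:
    return {
        int(row.condition_id): np.array([row.x, row.y])
        for row in layout.targets.itertuples()
    }


def circular_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal absolute angular difference, in [0, pi]."""
    d = np.abs(np.mod(a - b + np.pi, 2.0 * np.pi) - np.pi)
    return d


def decode_errors(
    result: DecodeResult, layout: TargetLayout, metric: str
) -> ErrorDistribution:
    """Turn condition-level predictions into geometric error distributions.

    ``angle``/``arc`` require ring geometry (all decoded targets on rings);
    arc errors are the angle scaled by the *true* target's ring radius, and
    the restricted arc mean keeps only errors within the error range of the
    smallest ring (at most half its circumference).  ``distance`` is the
    absolute difference of target distances.
    """
    pos = _condition_positions(layout)
    true_xy = np.array([pos[int(c)] for c in result.y_true])
    pred_xy = np.array([pos[int(c)] for c in result.y_pred])
    if metric in ("angle", "arc"):
        if not layout.ring_radii:
            raise ValueError(f"metric {metric!r} requires a ring layout")
        ang = circular_difference(
            np.arctan2(true_xy[:, 1], true_xy[:, 0]),
            np.arctan2(pred_xy[:, 1], pred_xy[:, 0]),
        )
        if metric == "angle":
            errors = ang
            return ErrorDistribution(metric=metric, errors=errors, mean=float(errors.mean()))
        radius = np.hypot(true_xy[:, 0], true_xy[:, 1])
        errors = ang * radius
        r_min = min(layout.ring_radii)
        cap = np.pi * r_min
        restricted = errors[errors <= cap]
        return ErrorDistribution(
            metric=metric,
            errors=errors,
            mean=float(errors.mean()),
            restricted_mean=float(restricted.mean()) if restricted.size else float("nan"),
            restricted_max=float(cap),
        )
    if metric == "distance":
        d_true = np.hypot(true_xy[:, 0], true_xy[:, 1])
        d_pred = np.hypot(pred_xy[:, 0], pred_xy[:, 1])
        errors = np.abs(d_true - d_pred)
        return ErrorDistribution(metric=metric, errors=errors, mean=float(errors.mean()))
    raise ValueError(f"unknown metric {metric!r}")


def ablate_to_plane(table: pd.DataFrame, model: SubspaceModel) -> np.ndarray:
    """Spatial-plane-only features: per-trial (x_neural, y_neural).

    Discards the speed axis and every residual dimension, removing speed
    information prior to classification.
    """
    centered = rate_matrix(table) - model.center
    return np.column_stack([centered @ model.axis_x, centered @ model.axis_y])


def variance_ratio_test(a, b) -> tuple[float, float]:
    """Two-sample variance-ratio F test (two-sided, larger variance on top)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if min(va, vb) == 0:
        raise ValueError("zero variance sample")
    if va >= vb:
        F, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    return float(F), float(p)


def per_distance_direction_accuracy(
    table: pd.DataFrame,
    layout: TargetLayout,
    features: Optional[np.ndarray] = None,
    folds: int = 10,
    seed: int = 0,
) -> dict[float, DecodeResult]:
    """Direction classification run separately on each ring of a multi-ring task."""
    if len(layout.ring_radii) < 2:
        raise ValueError("per-distance accuracy requires a multi-ring layout")
    X = rate_matrix(table) if features is None else np.asarray(features, float)
    dist = target_distances(table)
    out = {}
    for radius in sorted(layout.ring_radii):
        mask = np.isclose(dist, radius)
        out[float(radius)] = crossval_classify(
            X[mask], table.loc[mask, "condition_id"].to_numpy(), folds=folds, seed=seed
        )
    return out


def distance_classification(
    table: pd.DataFrame,
    features: Optional[np.ndarray] = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Distance decoding on line layouts, trained and tested per direction.

    Trials are grouped by (task, side of center); a classifier is
    cross-validated within each group and the distance errors are aggregated
    across groups.  Returns (per-trial |distance error| in cm, mean error,
    mean accuracy across groups).
    """
    X = rate_matrix(table) if features is None else np.asarray(features, float)
    xy = table[["target_x", "target_y"]].to_numpy(float)
    axis_coord = np.where(
        table["task"].to_numpy() == "horizontal", xy[:, 0], xy[:, 1]
    )
    side = np.sign(axis_coord)
    dist = target_distances(table)
    errors, accs = [], []
    for task in pd.unique(table["task"]):
        for s in (-1.0, 1.0):
            mask = (table["task"].to_numpy() == task) & (side == s)
            if not mask.any():
                continue
            res = crossval_classify(
                X[mask], dist[mask], folds=folds, seed=seed
            )
            errors.append(np.abs(res.y_true - res.y_pred))
            accs.append(res.accuracy)
    all_err = np.concatenate(errors)
    return all_err, float(all_err.mean()), float(np.mean(accs))
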