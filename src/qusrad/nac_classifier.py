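"""Response classification: K-NN, SVM-RBF and Fisher's linear discriminant with
sequential forward feature selection and leave-one-out cross-validation.

The protocol mirrors small-cohort radiomics practice: up to four features are
chosen greedily by leave-one-out (LOO) accuracy over the whole cohort, the
chosen feature set is evaluated by LOO (train-only standardization in every
fold), and performance is summarized by a confusion matrix, sensitivity /
specificity / accuracy, F1 and trapezoid ROC AUC.  Selection and tuning on the
full cohort reproduce the optimism profile of the published protocol; a nested
mode (selection re-run inside each fold) is provided for the honest estimate
and is off by default.

Positive class defaults to the responder label 'R' (configurable): the source
study never states its convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cohort_stats import ALL_FEATURES
from .rf_core import ValidationError

logger = logging.getLogger("qusrad")

__all__ = [
    "ClassifierSpec",
    "CVResult",
    "Metrics",
    "fit_predict",
    "loo_cv",
    "sequential_forward_selection",
    "tune_hyperparameters",
    "confusion_metrics",
    "roc_auc",
    "DEFAULT_GRIDS",
]

DEFAULT_GRIDS = {
    "KNN": {"k": (1, 3, 5, 7, 9)},
    "SVM-RBF": {
        "C": tuple(10.0**e for e in range(-1, 4)),
        "gamma": tuple(10.0**e for e in range(-3, 2)),
    },
    "FLD": {},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier choice and hyperparameters.

    kind: 'KNN' (odd k, Euclidean), 'SVM-RBF' (C, gamma) or 'FLD'
    (no hyperparameters; affine-invariant, so standardization is cosmetic).
    """

    kind: str = "KNN"
    k: int = 5
    C: float = 1.0
    gamma: float = 0.1
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("KNN", "SVM-RBF", "FLD"):
            raise ValidationError("kind must be KNN, SVM-RBF or FLD")
        if self.kind == "KNN" and (self.k < 1 or self.k % 2 == 0):
            raise ValidationError("KNN k must be odd and >= 1")
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be positive")


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _fld_train(X: np.ndarray, y: np.ndarray):
    """Fisher projection w = Sw^-1 (mu+ - mu-) and midpoint threshold."""
    Xp, Xn = X[y == 1], X[y == 0]
    mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for Xi, mi in ((Xp, mp), (Xn, mn)):
        d = Xi - mi
        Sw += d.T @ d
    tr = np.trace(Sw)
    ridge = 1e-6 * (tr if tr > 0 else 1.0)
    try:
        w = np.linalg.solve(Sw + ridge * np.eye(X.shape[1]), mp - mn)
    except np.linalg.LinAlgError:  # pragma: no cover
        logger.warning("singular within-class scatter; using pseudo-inverse")
        w = np.linalg.pinv(Sw) @ (mp - mn)
    thr = 0.5 * (mp @ w + mn @ w)
    return w, thr


def fit_predict(spec: ClassifierSpec, X_train, y_train, X_test):
    """Fit one classifier and score test rows.

    Returns ``(labels, scores)`` with labels in {0, 1} (1 = positive class)
    and a continuous score increasing with positive-class confidence:
    K-NN - fraction of positive neighbours; SVM-RBF - decision-function
    value; FLD - projection minus the midpoint threshold.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training set must contain both classes")
    if spec.standardize:
        X_train, X_test = _standardize(X_train, X_test)
    if spec.kind == "KNN":
        clf = KNeighborsClassifier(n_neighbors=min(spec.k, len(y_train)), metric="euclidean")
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, list(clf.classes_).index(1)]
        labels = (scores > 0.5).astype(int)
        # majority vote with odd k cannot tie, but guard the boundary
        ties = scores == 0.5
        if ties.any():
            labels[ties] = clf.predict(X_test[ties])
    elif spec.kind == "SVM-RBF":
        clf = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
        clf.fit(X_train, y_train)
        scores = clf.decision_function(X_test)
        labels = (scores > 0).astype(int)
    else:  # FLD
        w, thr = _fld_train(X_train, y_train)
        scores = X_test @ w - thr
        labels = (scores > 0).astype(int)
    return labels, np.asarray(scores, dtype=float)


@dataclass
class CVResult:
    """Per-patient leave-one-out predictions and scores."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    feature_names: tuple
    n_folds: int


def loo_cv(X, y, spec: ClassifierSpec, feature_names=()) -> CVResult:
    """Leave-one-out cross-validation: n folds, train-only standardization.

    The held-out patient never contributes to fitting or to the
    standardization statistics of its own fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValidationError("LOO needs at least 3 patients")
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        tr = np.arange(n) != i
        lab, sc = fit_predict(spec, X[tr], y[tr], X[i : i + 1])
        preds[i], scores[i] = lab[0], sc[0]
    return CVResult(
        y_true=y, y_pred=preds, scores=scores,
        feature_names=tuple(feature_names), n_folds=n,
    )


def _loo_accuracy(X, y, spec) -> float:
    cv = loo_cv(X, y, spec)
    return float(np.mean(cv.y_pred == cv.y_true))


def sequential_forward_selection(
    cohort: pd.DataFrame,
    spec: ClassifierSpec,
    max_features: int = 4,
    positive_class: str = "R",
    feature_names=ALL_FEATURES,
):
    """Greedy forward selection of at most ``max_features`` features.

    At each step the feature whose addition maximizes LOO accuracy is added;
    ties break toward the lowest feature index (deterministic); selection
    stops when no addition strictly improves accuracy.
    """
    y = (cohort["response"] == positive_class).to_numpy(dtype=int)
    if min(y.sum(), len(y) - y.sum()) < 2:
        raise ValidationError("need >= 2 patients per class")
    names = list(feature_names)
    Xall = cohort[names].to_numpy(dtype=float)
    selected: list[int] = []
    best_acc = -np.inf
    while len(selected) < max_features:
        step_best, step_idx = -np.inf, None
        for idx in range(len(names)):
            if idx in selected:
                continue
            acc = _loo_accuracy(Xall[:, selected + [idx]], y, spec)
            if acc > step_best:
                step_best, step_idx = acc, idx
        if step_idx is None or step_best <= best_acc:
            break
        selected.append(step_idx)
        best_acc = step_best
    return [names[i] for i in selected]


def tune_hyperparameters(
    cohort: pd.DataFrame,
    kind: str,
    features,
    positive_class: str = "R",
    grids: dict | None = None,
) -> ClassifierSpec:
    """Grid search maximizing LOO accuracy on the full cohort.

    Deterministic: the grid is scanned in a fixed order and ties keep the
    first (smallest) parameter values.
    """
    grid = (grids or DEFAULT_GRIDS)[kind]
    y = (cohort["response"] == positive_class).to_numpy(dtype=int)
    X = cohort[list(features)].to_numpy(dtype=float)
    base = ClassifierSpec(kind=kind)
    if not grid:
        return base
    best_spec, best_acc = base, -np.inf
    if kind == "KNN":
        candidates = [replace(base, k=k) for k in grid["k"]]
    else:
        candidates = [
            replace(base, C=C, gamma=g) for C in grid["C"] for g in grid["gamma"]
        ]
    for cand in candidates:
        acc = _loo_accuracy(X, y, cand)
        if acc > best_acc:
            best_acc, best_spec = acc, cand
    return best_spec


@dataclass
class Metrics:
    """Confusion-derived performance summary (rates in percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float


def confusion_metrics(cv: CVResult, auc: float = np.nan) -> Metrics:
    """Sensitivity, specificity, accuracy (percent) and F1 from LOO output."""
    y, p = cv.y_true, cv.y_pred
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValidationError("need at least one actual positive and negative")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / len(y)
    f1 = 2.0 * tp / (2.0 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sn, specificity=sp, accuracy=acc, f1=f1, auc=auc,
    )


def roc_auc(scores, labels):
    """ROC curve by threshold sweep and trapezoid AUC.

    Returns ``(points, auc)`` where points is an (m, 2) array of
    (FPR, TPR) pairs.  The trapezoid AUC over the sweep equals the
    Mann-Whitney pair-counting statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    if np.ptp(scores) == 0:
        logger.warning("constant scores: degenerate ROC, AUC = 0.5")
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        return pts, 0.5
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # collapse tied thresholds
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
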