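"""SVM classification protocol and evaluation metrics.

Feature vectors are scaled per feature to [-1, 1] (fit on training data
only), classified with an RBF-kernel support vector machine whose
regularization ``C`` and kernel width ``gamma`` are chosen by grid search
with stratified k-fold cross-validation (k = 10), and evaluated by
leave-one-out cross-validation and by out-of-bag bootstrap resampling.

Malignant is the positive class throughout.  Seven criteria are reported:
the area under the ROC curve (AUC, computed from SVM decision values) and
the six confusion-matrix statistics

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    SENS = TP / (TP + FN)            SPEC = TN / (TN + FP)
    PPV  = TP / (TP + FP)            NPV  = TN / (TN + FN)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric with zero denominator is reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "SVMConfig",
    "FeatureScaler",
    "scale_features",
    "default_grid",
    "grid_search_svm",
    "loo_cv",
    "bootstrap_eval",
    "confusion_metrics",
    "roc_auc",
]

METRIC_NAMES = ("auc", "acc", "sens", "spec", "ppv", "npv", "mcc")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; malignant is the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class EvalReport:
    """The seven evaluation criteria plus the underlying confusion matrix."""

    auc: float
    acc: float
    sens: float
    spec: float
    ppv: float
    npv: float
    mcc: float
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyper-parameters and the CV protocol that selected them."""

    C: float
    gamma: float
    k: int = 10
    seed: int = 0
    cv_accuracy: float | None = None

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _as_binary_labels(labels) -> np.ndarray:
    """Coerce labels to {0, 1} with malignant = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        mapping = {"benign": 0, "malignant": 1, "0": 0, "1": 1}
        try:
            return np.array([mapping[str(v).strip().lower()] for v in arr])
        except KeyError as exc:
            raise ValueError(f"unrecognized class label {exc}") from None
    out = arr.astype(int)
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError("numeric labels must be 0 (benign) or 1 (malignant)")
    return out


class FeatureScaler:
    """Per-feature affine map fitted on training data: min -> -1, max -> +1.

    Constant training features map to 0 everywhere (any value in [-1, 1]
    would be consistent; 0 is the symmetric choice).  Test values outside
    the training range extend beyond [-1, 1] without clipping.
    """

    def __init__(self):
        self.lo_ = None
        self.hi_ = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("expected a non-empty 2-D feature matrix")
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo_ is None:
            raise RuntimeError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        span = self.hi_ - self.lo_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = -1.0 + 2.0 * (X[:, nz] - self.lo_[nz]) / span[nz]
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_features(train: np.ndarray, test: np.ndarray | None = None):
    """Scale features to [-1, 1] using training statistics only.

    Returns ``(train_scaled, test_scaled, scaler)``; ``test_scaled`` is
    None when no test table is given.
    """
    scaler = FeatureScaler()
    train_scaled = scaler.fit_transform(train)
    test_scaled = scaler.transform(test) if test is not None else None
    return train_scaled, test_scaled, scaler


def default_grid(step: float = 2.0):
    """Log2-spaced (C, gamma) candidate grid.

    C in 2^-5 .. 2^15 and gamma in 2^-15 .. 2^3, with ``step`` the exponent
    increment (2 for the coarse grid, 0.5 for the fine half-step grid).
    """
    c_exp = np.arange(-5.0, 15.0 + 1e-9, step)
    g_exp = np.arange(-15.0, 3.0 + 1e-9, step)
    return 2.0**c_exp, 2.0**g_exp


class _ScaledSVM:
    """RBF-SVM with its training-set feature scaler frozen in."""

    def __init__(self, scaler: FeatureScaler, svc: SVC):
        self.scaler = scaler
        self.svc = svc

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(X))


def _fit_svm(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> _ScaledSVM:
    scaler = FeatureScaler()
    Xs = scaler.fit_transform(np.asarray(X, dtype=float))
    svc = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
    svc.fit(Xs, y)
    return _ScaledSVM(scaler, svc)


def grid_search_svm(
    features: np.ndarray,
    labels,
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> SVMConfig:
    """Choose (C, gamma) maximizing mean stratified k-fold CV accuracy.

    Scaling is refitted on each training fold to avoid leakage.  Ties are
    broken toward smaller C, then smaller gamma.  Requires at least ``k``
    samples in each class.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary_labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search requires both classes present")
    if counts.min() < k:
        raise ValueError(f"need >= {k} samples per class for {k}-fold CV")
    if C_grid is None or gamma_grid is None:
        dc, dg = default_grid()
        C_grid = dc if C_grid is None else np.asarray(C_grid, dtype=float)
        gamma_grid = dg if gamma_grid is None else np.asarray(gamma_grid, dtype=float)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(X, y):
        scaler = FeatureScaler().fit(X[tr])
        folds.append((scaler.transform(X[tr]), y[tr], scaler.transform(X[te]), y[te]))

    best = None  # (accuracy, C, gamma)
    for C, gamma in product(sorted(C_grid), sorted(gamma_grid)):
        correct = total = 0
        for Xtr, ytr, Xte, yte in folds:
            svc = SVC(kernel="rbf", C=C, gamma=gamma)
            svc.fit(Xtr, ytr)
            correct += int((svc.predict(Xte) == yte).sum())
            total += yte.size
        acc = correct / total
        if best is None or acc > best[0] + 1e-12:
            best = (acc, C, gamma)
    return SVMConfig(C=best[1], gamma=best[2], k=k, seed=seed, cv_accuracy=best[0])


def confusion_metrics(cm: ConfusionMatrix) -> EvalReport:
    """Evaluate the six confusion-matrix criteria exactly (AUC is NaN)."""
    tp, fn, tn, fp = cm.tp, cm.fn, cm.tn, cm.fp
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative case")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return EvalReport(
        auc=math.nan,
        acc=ratio(tp + tn, cm.n),
        sens=ratio(tp, tp + fn),
        spec=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
        confusion=cm,
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve from continuous decision scores.

    Equals the probability that a random positive case outscores a random
    negative one, with ties counted one half (trapezoidal ROC integration).
    """
    y = _as_binary_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _report_from_scores(
    y: np.ndarray, scores: np.ndarray, preds: np.ndarray
) -> EvalReport:
    cm = ConfusionMatrix(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
    )
    report = confusion_metrics(cm)
    report.auc = roc_auc(scores, y)
    return report


def loo_cv(
    features: np.ndarray,
    labels,
    config: SVMConfig,
    nested_grid: bool = False,
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
):
    """Leave-one-out cross-validation of the scaled RBF-SVM.

    Each of the n iterations refits the feature scaler (and, when
    ``nested_grid`` is set, reruns the grid search) on the n-1 training
    cases and scores the held-out case with the SVM decision function.
    Returns ``(scores, EvalReport)`` where the report pools all n held-out
    scores and thresholded predictions.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary_labels(labels)
    n = y.size
    if n < 3:
        raise ValueError("LOO-CV requires at least 3 cases")
    if np.unique(y).size < 2:
        raise ValueError("LOO-CV requires both classes present")

    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        cfg = config
        if nested_grid:
            cfg = grid_search_svm(
                X[train], y[train], C_grid, gamma_grid, k=config.k, seed=config.seed
            )
        model = _fit_svm(X[train], y[train], cfg)
        scores[i] = model.decision_function(X[i : i + 1])[0]
        preds[i] = int(scores[i] > 0)
    return scores, _report_from_scores(y, scores, preds)


def bootstrap_eval(
    features: np.ndarray,
    labels,
    config: SVMConfig,
    B: int = 500,
    seed: int = 0,
):
    """Out-of-bag bootstrap evaluation.

    Each replicate draws n cases with replacement as training data and
    tests on the cases not drawn (on average ~63.2% of cases are in-bag).
    Replicates whose out-of-bag set lacks a class are redrawn; the number
    of redraws is recorded.  Returns ``(per_replicate, summary, n_redrawn)``
    where ``per_replicate`` holds one row of the seven metrics per
    replicate and ``summary`` their mean and standard deviation.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    X = np.asarray(features, dtype=float)
    y = _as_binary_labels(labels)
    n = y.size
    if n < 10:
        raise ValueError("bootstrap evaluation requires n >= 10")
    rng = np.random.default_rng(seed)

    rows = []
    n_redrawn = 0
    for _ in range(B):
        while True:
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size > 0 and np.unique(y[oob]).size == 2 and np.unique(y[boot]).size == 2:
                break
            n_redrawn += 1
        model = _fit_svm(X[boot], y[boot], config)
        s = model.decision_function(X[oob])
        report = _report_from_scores(y[oob], s, (s > 0).astype(int))
        row = report.as_dict()
        row["oob_n"] = oob.size
        rows.append(row)

    per_replicate = pd.DataFrame(rows)
    summary = per_replicate[list(METRIC_NAMES)].agg(["mean", "std"])
    return per_replicate, summary, n_redrawn
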