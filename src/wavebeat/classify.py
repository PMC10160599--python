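"""RBF-kernel support-vector classification with stratified splitting and
cross-validated grid search over (C, gamma).

The Gaussian kernel exp(-gamma * ||u - v||^2) lets the maximal-margin
classifier separate beat classes that are not linearly separable in the
wavelet-coefficient space. C trades margin width against training error;
gamma sets the kernel length-scale. Both are tuned by exhaustive grid
search scored with stratified k-fold accuracy, strictly inside the training
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import SchemaError
from .features import FeatureMatrix

MODEL_FORMAT = "wavebeat-svm-v1"


@dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0
    gamma: float = 0.01
    kernel: str = "rbf"

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")


@dataclass
class GridSpec:
    C_values: tuple = (0.1, 1.0, 10.0, 100.0, 1000.0)
    gamma_values: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.C_values or not self.gamma_values:
            raise ValueError("grid value lists must be non-empty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


class RbfSvmClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian-kernel SVM (sklearn estimator API; positive class = abnormal).

    Fitted attributes expose the dual solution: ``support_vectors_``,
    ``dual_coef_``, ``intercept_``. ``decision_function`` returns signed
    margins (positive => class 1) for ROC sweeps.
    """

    def __init__(self, C: float = 1.0, gamma: float = 0.01):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("need >= 2 items in each of two classes to fit")
        if np.all(X == X[0]):
            raise ValueError(
                "degenerate training set: all feature rows identical; "
                "the maximal-margin problem has no solution"
            )
        self._svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self._svc.fit(X, y)
        self.classes_ = self._svc.classes_
        self.support_vectors_ = self._svc.support_vectors_
        self.dual_coef_ = self._svc.dual_coef_
        self.intercept_ = self._svc.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (X.size and X.shape[1] != self.n_features_in_):
            raise SchemaError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        return X

    def predict(self, X) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self._svc.predict(X)

    def decision_function(self, X) -> np.ndarray:
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self._svc.decision_function(X)

    # -- serialization ----------------------------------------------------
    def save(self, path) -> Path:
        path = Path(path)
        joblib.dump({"format": MODEL_FORMAT, "params": self.get_params(),
                     "svc": self._svc}, path)
        return path

    @classmethod
    def load(cls, path) -> "RbfSvmClassifier":
        payload = joblib.load(path)
        if payload.get("format") != MODEL_FORMAT:
            raise SchemaError(f"unrecognized model format in {path}")
        model = cls(**payload["params"])
        model._svc = payload["svc"]
        model.classes_ = model._svc.classes_
        model.support_vectors_ = model._svc.support_vectors_
        model.dual_coef_ = model._svc.dual_coef_
        model.intercept_ = model._svc.intercept_
        model.n_features_in_ = model._svc.n_features_in_
        return model


def fit_svm(features: FeatureMatrix, config: SVMConfig) -> RbfSvmClassifier:
    if features.y is None:
        raise ValueError("training features carry no labels")
    return RbfSvmClassifier(C=config.C, gamma=config.gamma).fit(features.X, features.y)


def predict(model: RbfSvmClassifier, features: FeatureMatrix):
    """Labels plus decision scores (for ROC)."""
    return model.predict(features.X), model.decision_function(features.X)


def stratified_split(features: FeatureMatrix, test_fraction: float, seed: int = 0):
    """Deterministic stratified train/test split of a labelled FeatureMatrix."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    y = features.y
    if y is None:
        raise ValueError("cannot stratify unlabelled features")
    if len(np.unique(y)) < 2:
        raise ValueError("stratification requires both classes present")
    idx = np.arange(features.n_beats)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return features.take(np.sort(train_idx)), features.take(np.sort(test_idx))


def grid_search_cv(features: FeatureMatrix, grid: GridSpec = GridSpec()):
    """Exhaustive (C, gamma) search scored by stratified k-fold mean accuracy.

    Ties are broken toward the smaller C, then the smaller gamma (the
    simpler model), which the ascending iteration order guarantees. Returns
    ``(best SVMConfig, results DataFrame)`` with per-fold accuracies kept
    for audit.
    """
    X, y = features.X, features.y
    if y is None:
        raise ValueError("grid search requires labelled features")
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or grid.k_folds > counts.min():
        raise ValueError(
            f"k_folds={grid.k_folds} exceeds the minority class count {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=grid.k_folds, shuffle=True, random_state=grid.seed)
    folds = list(cv.split(X, y))
    rows = []
    best = None
    for C in sorted(grid.C_values):
        for gamma in sorted(grid.gamma_values):
            fold_acc = []
            for train_idx, val_idx in folds:
                model = RbfSvmClassifier(C=C, gamma=gamma).fit(X[train_idx], y[train_idx])
                fold_acc.append(float(np.mean(model.predict(X[val_idx]) == y[val_idx])))
            mean_acc = float(np.mean(fold_acc))
            rows.append({"C": C, "gamma": gamma, "mean_accuracy": mean_acc,
                         **{f"fold{i}_accuracy": a for i, a in enumerate(fold_acc)}})
            if best is None or mean_acc > best[0]:
                best = (mean_acc, SVMConfig(C=C, gamma=gamma))
    results = pd.DataFrame(rows)
    return best[1], results
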