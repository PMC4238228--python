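"""One-against-all RBF-SVM classification, cross-validation and method comparison.

One binary RBF-kernel SVM is trained per class (that class against the
rest); a sample is assigned to the class with the largest decision value,
ties broken by class order (classes sorted lexicographically).  Performance
is estimated with stratified five-fold cross-validation in which the entire
feature-selection stage (PCA + DB-guided dimensionality choice) is refit on
the four training folds only.  Because no canonical values exist for the
RBF hyperparameters, they are tuned per outer fold by an inner 3-fold grid
search over a small log grid (overridable, or fixable to constants).

Feature-method comparisons use one-way fixed-effects ANOVA on groups of
per-run accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix
from .selection import fit_pca, select_k, transform


class TrainingError(ValueError):
    """Training set does not support the requested model."""


class UndefinedStatisticError(ValueError):
    """Test statistic undefined for the given data."""


DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold accuracies and pooled confusion."""

    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    confusion: np.ndarray
    classes: list[str]
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean_accuracy": float(self.mean_accuracy),
            "std_accuracy": float(self.std_accuracy),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "config_echo": self.config_echo,
        }


def train_ova(
    Z_train: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    gamma: float | str = "scale",
    classes: Sequence[str] | None = None,
) -> OneVsRestClassifier:
    """Fit one RBF-SVM per class (one-against-all).

    The returned classifier exposes ``decision_function`` (one score per
    class per row, columns in sorted class order) and ``predict`` (argmax,
    first class on ties).
    """
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    if classes is not None:
        missing = [c for c in classes if c not in present]
        if missing:
            raise TrainingError(f"class {missing[0]!r} absent from training data")
    if len(present) < 2:
        raise TrainingError("need at least 2 classes to train a classifier")
    clf = OneVsRestClassifier(SVC(kernel="rbf", C=C, gamma=gamma))
    clf.fit(Z_train, labels)
    return clf


def tune_and_train(
    Z_train: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 3,
) -> GridSearchCV:
    """Inner-CV grid search over (C, gamma) for the one-against-all SVM."""
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        OneVsRestClassifier(SVC(kernel="rbf")),
        param_grid={
            "estimator__C": list(c_grid),
            "estimator__gamma": list(gamma_grid),
        },
        cv=inner,
        n_jobs=None,
    )
    search.fit(Z_train, labels)
    return search


def cross_validate(
    features: FeatureMatrix,
    n_folds: int = 5,
    seed: int = 0,
    var_threshold: float = 0.9,
    C: float | None = None,
    gamma: float | None = None,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> CVResult:
    """Stratified k-fold cross-validation of the selection + OvA-SVM pipeline.

    Per fold, PCA fitting, DB-guided dimensionality choice and SVM training
    (including any hyperparameter search) see only the training folds; the
    held-out fold is projected with the training mean/loadings and scored.
    Fixing both ``C`` and ``gamma`` skips the inner grid search.
    """
    X, y = features.X, np.asarray(features.labels)
    classes = sorted(np.unique(y).tolist())
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < n_folds:
        warnings.warn(
            f"class counts {counts} below n_folds={n_folds}; "
            "falling back to unstratified folds"
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracies: list[float] = []
    k_per_fold: list[int] = []
    params_per_fold: list[dict] = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        model = fit_pca(X[train_idx])
        model = select_k(model, X[train_idx], y[train_idx], var_threshold)
        Z_train = transform(model, X[train_idx])
        Z_test = transform(model, X[test_idx])
        if C is not None and gamma is not None:
            clf = train_ova(Z_train, y[train_idx], C=C, gamma=gamma, classes=classes)
            params_per_fold.append({"C": C, "gamma": gamma})
        else:
            search = tune_and_train(
                Z_train, y[train_idx], seed=seed + fold,
                c_grid=c_grid, gamma_grid=gamma_grid,
            )
            clf = search
            params_per_fold.append(
                {
                    "C": search.best_params_["estimator__C"],
                    "gamma": search.best_params_["estimator__gamma"],
                }
            )
        pred = clf.predict(Z_test)
        accuracies.append(float(np.mean(pred == y[test_idx])))
        k_per_fold.append(int(model.k))
        confusion += confusion_matrix(y[test_idx], pred, labels=classes)
    acc = np.asarray(accuracies)
    return CVResult(
        per_fold_accuracy=acc,
        mean_accuracy=float(acc.mean()),
        std_accuracy=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        confusion=confusion,
        classes=classes,
        config_echo={
            "n_folds": n_folds,
            "seed": seed,
            "var_threshold": var_threshold,
            "k_per_fold": k_per_fold,
            "svm_params_per_fold": params_per_fold,
            "method": features.method,
            "n_segments": int(X.shape[0]),
            "n_features": int(X.shape[1]),
        },
    )


def compare_methods(accuracy_groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across groups of per-run accuracies.

    Returns the F statistic and p-value.  Identical groups with nonzero
    within-group variance give F = 0, p = 1; fully degenerate data (zero
    within- and between-group variance) has no defined F.
    """
    groups = [np.asarray(g, dtype=float) for g in accuracy_groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.var(pooled) == 0.0:
        raise UndefinedStatisticError(
            "all values identical: F statistic undefined (0/0)"
        )
    f_stat, p_value = stats.f_oneway(*groups)
    return float(f_stat), float(p_value)
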