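"""PCA feature selection guided by the Davies-Bouldin cluster-validity index.

The 32-dimensional relative-energy features are projected on their leading
principal components.  The retained dimensionality ``k`` is chosen by
evaluating the Davies-Bouldin (DB) index of the class structure in every
candidate subspace ``k = 1..n_features`` and taking the ``k`` that minimises
DB among those whose cumulative explained variance reaches the 90%
threshold.  DB is a dimensionless within-scatter / between-separation
ratio; lower means better-separated classes, and it need not vary
monotonically with dimensionality, so the full trace is always evaluated.

Selection must always be fitted on training data only and applied to held
out data with the training mean and loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .features import FeatureMatrix


class DegenerateVarianceError(ValueError):
    """Feature matrix has (numerically) no variance to decompose."""


@dataclass
class SelectionModel:
    """Fitted PCA basis plus the DB-guided choice of dimensionality.

    ``loadings`` rows are principal axes ordered by decreasing explained
    variance; ``k`` is unset (None) until :func:`select_k` has run, after
    which ``db_trace[j]`` holds the DB index of the leading ``j + 1``
    components on the training data.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    variance_ratios: np.ndarray
    k: int | None = None
    db_trace: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_features(self) -> int:
        return self.loadings.shape[1]


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_pca(X_train: FeatureMatrix | np.ndarray) -> SelectionModel:
    """Mean-centred PCA of the training features (no rescaling).

    Relative-energy features are already commensurate (simplex-valued), so
    only centring is applied.
    """
    data = _as_array(X_train)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    total_var = float(np.var(data, axis=0).sum())
    if total_var <= 1e-300:
        raise DegenerateVarianceError("feature matrix is constant; PCA undefined")
    pca = PCA(svd_solver="full")
    pca.fit(data)
    return SelectionModel(
        mean_vector=pca.mean_.copy(),
        loadings=pca.components_.copy(),
        variance_ratios=pca.explained_variance_ratio_.copy(),
    )


def db_index(Z: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index of the labelled point cloud ``Z``.

    ``DB = (1/C) * sum_c max_{c' != c} (S_c + S_c') / d_cc'`` where ``S_c``
    is the mean Euclidean distance of class-c points to their centroid and
    ``d_cc'`` the distance between centroids.  Lower values indicate higher
    class separability.  Coincident centroids of two classes make the ratio
    unbounded; the index is then +inf with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("db_index needs at least 2 classes")
    centroids = np.stack([Z[labels == c].mean(axis=0) for c in classes])
    scatter = np.array(
        [
            float(np.mean(np.linalg.norm(Z[labels == c] - centroids[i], axis=1)))
            for i, c in enumerate(classes)
        ]
    )
    dist = cdist(centroids, centroids)
    off_diag = ~np.eye(classes.size, dtype=bool)
    if np.any(dist[off_diag] == 0.0):
        warnings.warn("coincident class centroids; DB index is infinite")
        return float("inf")
    ratios = (scatter[:, None] + scatter[None, :]) / np.where(off_diag, dist, np.inf)
    return float(np.mean(ratios.max(axis=1)))


def select_k(
    model: SelectionModel,
    X_train: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    var_threshold: float = 0.9,
) -> SelectionModel:
    """Choose the retained dimensionality ``k`` on training data.

    For each candidate ``k`` the DB index of the leading-``k`` projection is
    recorded; among candidates whose cumulative explained variance reaches
    ``var_threshold``, the ``k`` with minimal DB is chosen (smallest ``k``
    on ties).  If no candidate reaches the threshold, ``k`` falls back to
    all components with a warning.
    """
    if labels is None and isinstance(X_train, FeatureMatrix):
        labels = X_train.labels
    if labels is None:
        raise ValueError("labels are required to evaluate the DB index")
    data = _as_array(X_train)
    Z = (data - model.mean_vector) @ model.loadings.T
    n_comp = model.n_components
    trace = np.array([db_index(Z[:, : j + 1], labels) for j in range(n_comp)])
    cumvar = np.cumsum(model.variance_ratios)
    feasible = np.flatnonzero(cumvar >= var_threshold - 1e-12)
    if feasible.size == 0:
        warnings.warn(
            f"no dimensionality reaches cumulative variance {var_threshold}; "
            f"keeping all {n_comp} components"
        )
        chosen = n_comp
    else:
        chosen = int(feasible[np.argmin(trace[feasible])]) + 1
    return replace(model, k=chosen, db_trace=trace)


def transform(model: SelectionModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Centre with the *training* mean and project on the first ``k`` axes."""
    if model.k is None:
        raise ValueError("model.k is unset; run select_k first")
    data = _as_array(X)
    if data.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {data.shape[1]}"
        )
    return (data - model.mean_vector) @ model.loadings[: model.k].T
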