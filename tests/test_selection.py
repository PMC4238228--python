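"""PCA fitting, Davies-Bouldin index, and DB-guided dimensionality choice."""

import numpy as np
import pytest

from semgkit.selection import (
    DegenerateVarianceError,
    db_index,
    fit_pca,
    select_k,
    transform,
)


def brute_force_db(Z, labels):
    """Independent loop-based evaluation of the Davies-Bouldin formula."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 1:
        Z = Z.T
    classes = sorted(set(labels))
    cent, scat = {}, {}
    for c in classes:
        pts = np.array([z for z, l in zip(Z, labels) if l == c])
        cent[c] = pts.mean(axis=0)
        scat[c] = np.mean([np.linalg.norm(p - cent[c]) for p in pts])
    total = 0.0
    for c in classes:
        worst = -np.inf
        for c2 in classes:
            if c2 == c:
                continue
            d = np.linalg.norm(cent[c] - cent[c2])
            worst = max(worst, (scat[c] + scat[c2]) / d)
        total += worst
    return total / len(classes)


class TestFitPca:
    def test_isotropic_cloud_splits_variance_evenly(self, rng):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        X = rng.normal(size=(20000, 2)) @ rot.T
        model = fit_pca(X)
        np.testing.assert_allclose(model.variance_ratios, [0.5, 0.5], atol=0.02)

    def test_rank_one_data_concentrates_variance(self, rng):
        direction = np.array([1.0, 2.0, -1.0, 0.5])
        X = rng.normal(size=(50, 1)) * direction + 3.0
        model = fit_pca(X)
        np.testing.assert_allclose(model.variance_ratios[0], 1.0, atol=1e-12)
        np.testing.assert_allclose(model.variance_ratios[1:], 0.0, atol=1e-12)

    def test_full_back_projection_reproduces_centred_data(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_pca(X)
        Z = (X - model.mean_vector) @ model.loadings.T
        back = Z @ model.loadings
        np.testing.assert_allclose(back, X - model.mean_vector, atol=1e-9)

    def test_variance_ratios_sorted_and_bounded(self, rng):
        model = fit_pca(rng.normal(size=(100, 10)) * rng.uniform(0.1, 3, 10))
        assert np.all(np.diff(model.variance_ratios) <= 1e-12)
        assert model.variance_ratios.sum() <= 1 + 1e-9

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            fit_pca(np.full((10, 4), 2.0))


class TestDbIndex:
    def test_zero_scatter_distinct_centroids_gives_zero(self):
        Z = np.array([[0.0, 0], [0, 0], [4, 0], [4, 0]])
        assert db_index(Z, np.array(["a", "a", "b", "b"])) == 0.0

    def test_two_1d_clusters_closed_form(self):
        # scatter 1 each, centroid gap 4 -> (1+1)/4 = 0.5 exactly
        Z = np.array([-1.0, 1.0, 3.0, 5.0])
        assert db_index(Z, np.array(["a", "a", "b", "b"])) == 0.5

    def test_matches_brute_force_on_random_datasets(self, rng):
        for _ in range(50):
            n_classes = rng.integers(2, 5)
            labels = rng.integers(0, n_classes, size=30)
            if len(set(labels)) < 2:
                continue
            Z = rng.normal(size=(30, rng.integers(1, 6)))
            assert db_index(Z, labels) == pytest.approx(
                brute_force_db(Z, labels), abs=1e-12
            )

    def test_coincident_centroids_warn_and_return_inf(self):
        Z = np.array([[0.0, 1], [0, -1], [0, 2], [0, -2]])
        labels = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="coincident"):
            assert db_index(Z, labels) == np.inf

    def test_invariant_to_rotation_translation_and_scale(self, rng):
        Z = rng.normal(size=(60, 3)) + np.repeat(np.eye(3) * 4, 20, axis=0)
        labels = np.repeat(["a", "b", "c"], 20)
        base = db_index(Z, labels)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert db_index(Z @ q + 7.5, labels) == pytest.approx(base, rel=1e-10)
        assert db_index(Z * 123.4, labels) == pytest.approx(base, rel=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            db_index(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_pure_noise_dimension_does_not_improve_db(self, rng):
        worse = 0
        for rep in range(20):
            Z = rng.normal(size=(80, 1)) + np.repeat([0.0, 4.0], 40)[:, None]
            labels = np.repeat(["a", "b"], 40)
            with_noise = np.hstack([Z, rng.normal(size=(80, 1))])
            worse += db_index(with_noise, labels) >= db_index(Z, labels)
        assert worse >= 18  # noise dimensions add scatter, not separation


class TestSelectK:
    def test_structure_on_pc1_selects_k1(self, rng):
        # class split along a high-variance first axis; the rest is faint noise
        n = 200
        labels = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 6)) * 0.05
        X[:, 0] += np.where(labels == "a", -5.0, 5.0)
        model = select_k(fit_pca(X), X, labels, var_threshold=0.9)
        assert model.k == 1
        assert model.db_trace is not None and model.db_trace.shape == (6,)

    def test_zero_threshold_gives_global_argmin(self, rng):
        X = rng.normal(size=(100, 5))
        X[:50, 0] += 4.0
        labels = np.repeat(["a", "b"], 50)
        model = select_k(fit_pca(X), X, labels, var_threshold=0.0)
        assert model.k == int(np.argmin(model.db_trace)) + 1

    def test_variance_constraint_filters_low_k(self, rng):
        # DB is best at k=1 but cumulative variance forces a larger k
        n = 300
        labels = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 4))
        X[:, 0] = X[:, 0] * 0.3 + np.where(labels == "a", -3.0, 3.0) * 0.3
        model = fit_pca(X)
        chosen = select_k(model, X, labels, var_threshold=0.95)
        cumvar = np.cumsum(chosen.variance_ratios)
        assert cumvar[chosen.k - 1] >= 0.95

    def test_infeasible_threshold_warns_and_keeps_all(self, rng):
        X = rng.normal(size=(50, 4))
        labels = np.repeat(["a", "b"], 25)
        model = fit_pca(X)
        with pytest.warns(UserWarning, match="cumulative variance"):
            chosen = select_k(model, X, labels, var_threshold=1.5)
        assert chosen.k == model.n_components


class TestTransform:
    def test_projected_training_variance_matches_ratios(self, rng):
        X = rng.normal(size=(500, 6)) * np.array([3.0, 2, 1, 0.5, 0.2, 0.1])
        labels = np.repeat(["a", "b"], 250)
        model = select_k(fit_pca(X), X, labels, var_threshold=0.0)
        Z = transform(model, X)
        total = np.var(X - X.mean(axis=0), axis=0).sum()
        expected = model.variance_ratios[: model.k] * total * 500 / 499
        np.testing.assert_allclose(np.var(Z, axis=0, ddof=1), expected, rtol=1e-8)

    def test_training_mean_row_maps_to_origin(self, rng):
        X = rng.normal(size=(30, 5)) + 10.0
        labels = np.repeat(["a", "b"], 15)
        model = select_k(fit_pca(X), X, labels, var_threshold=0.0)
        z = transform(model, model.mean_vector[None, :])
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_test_rows_centred_with_training_mean(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.repeat(["a", "b"], 15)
        model = select_k(fit_pca(X), X, labels, var_threshold=0.0)
        X_test = rng.normal(size=(10, 5)) + 100.0  # far from training mean
        Z = transform(model, X_test)
        manual = (X_test - model.mean_vector) @ model.loadings[: model.k].T
        np.testing.assert_allclose(Z, manual)
        assert np.abs(Z).max() > 10  # offset not absorbed by per-set centring

    def test_feature_count_mismatch_rejected(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.repeat(["a", "b"], 15)
        model = select_k(fit_pca(X), X, labels)
        with pytest.raises(ValueError, match="features"):
            transform(model, rng.normal(size=(4, 6)))
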