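"""KPCA + Ridge: closed forms, oracle equivalence, limits, scaling."""

import time

import numpy as np
import pytest
from sklearn.decomposition import KernelPCA
from sklearn.linear_model import RidgeClassifier

from collarml import kpca


def naive_kpca_components(X, gamma, n_components):
    """Independent oracle: explicit kernel, centering matrix H K H, dense
    eigensolver, components scaled by sqrt(eigenvalue)."""
    n = len(X)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * sq)
    H = np.eye(n) - np.ones((n, n)) / n
    w, v = np.linalg.eigh(H @ K @ H)
    idx = np.argsort(w)[::-1][:n_components]
    return v[:, idx] * np.sqrt(w[idx])


def assert_equal_up_to_sign(A, B, atol=1e-6):
    for j in range(A.shape[1]):
        s = np.sign(np.dot(A[:, j], B[:, j])) or 1.0
        np.testing.assert_allclose(A[:, j], s * B[:, j], atol=atol)


class TestFitKPCA:
    def test_two_point_kernel_closed_form(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        gamma = 0.1
        K = kpca.rbf_kernel_matrix(X, X, gamma)
        assert K[0, 1] == pytest.approx(np.exp(-gamma * 25.0))
        assert K[0, 0] == pytest.approx(1.0)

    def test_duplicated_points_project_identically(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        Xdup = np.vstack([X, X])
        m = kpca.fit_kpca(Xdup, gamma=0.5, n_components=5)
        np.testing.assert_allclose(m.train_components[:10],
                                   m.train_components[10:], atol=1e-8)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        m = kpca.fit_kpca(X, gamma=0.3, n_components=8)
        assert_equal_up_to_sign(m.train_components,
                                naive_kpca_components(X, 0.3, 8))

    def test_matches_sklearn_out_of_sample(self):
        rng = np.random.default_rng(2)
        X, Xt = rng.normal(size=(25, 5)), rng.normal(size=(8, 5))
        m = kpca.fit_kpca(X, gamma=0.2, n_components=6)
        sk = KernelPCA(n_components=6, kernel="rbf", gamma=0.2).fit(X)
        assert_equal_up_to_sign(m.train_components, sk.transform(X))
        # align signs column-wise via the training projections, then compare
        P, P_sk = m.train_components, sk.transform(X)
        signs = np.array([np.sign(np.dot(P[:, j], P_sk[:, j])) for j in range(6)])
        np.testing.assert_allclose(kpca.project_kpca(m, Xt),
                                   sk.transform(Xt) * signs, atol=1e-8)

    def test_eigenvalues_sorted_and_positive(self):
        rng = np.random.default_rng(3)
        m = kpca.fit_kpca(rng.normal(size=(15, 3)), gamma=1.0)
        assert np.all(np.diff(m.eigenvalues) <= 0)
        assert np.all(m.eigenvalues > 0)

    def test_degenerate_identical_points(self):
        X = np.ones((6, 3))
        with pytest.raises(kpca.DegenerateKernelError):
            kpca.fit_kpca(X, gamma=1.0)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            kpca.fit_kpca(np.eye(3), gamma=0.0)


class TestProject:
    def test_train_projection_self_consistent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(18, 4))
        m = kpca.fit_kpca(X, gamma=0.4)
        np.testing.assert_allclose(kpca.project_kpca(m, X),
                                   m.train_components, atol=1e-8)
        assert np.abs(m.train_components.mean(axis=0)).max() < 1e-8

    def test_point_equal_to_training_point(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        m = kpca.fit_kpca(X, gamma=0.4)
        np.testing.assert_allclose(kpca.project_kpca(m, X[3:4])[0],
                                   m.train_components[3], atol=1e-8)

    def test_dimension_mismatch(self):
        m = kpca.fit_kpca(np.random.default_rng(0).normal(size=(8, 3)), 0.5)
        with pytest.raises(ValueError):
            kpca.project_kpca(m, np.zeros((2, 4)))


class TestRidge:
    def test_separable_clusters_train_accuracy_one(self):
        rng = np.random.default_rng(6)
        C = np.vstack([rng.normal(-3, 0.2, size=(20, 2)),
                       rng.normal(3, 0.2, size=(20, 2))])
        y = np.array(["A"] * 20 + ["B"] * 20)
        m = kpca.fit_ridge(C, y, alpha=0.1)
        pred = m.classes[kpca.ridge_scores(m, C).argmax(axis=1)]
        assert (pred == y).all()

    def test_huge_alpha_collapses_to_intercept(self):
        rng = np.random.default_rng(7)
        C = rng.normal(size=(30, 3))
        y = np.array(["A"] * 10 + ["B"] * 20)
        m = kpca.fit_ridge(C, y, alpha=1e9)
        assert np.abs(m.weights).max() < 1e-5
        pred = m.classes[kpca.ridge_scores(m, rng.normal(size=(50, 3))).argmax(axis=1)]
        assert set(pred) == {"B"}  # majority class wins on intercepts

    def test_one_dimensional_boundary_at_zero(self):
        C = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array(["A", "A", "B", "B"])
        m = kpca.fit_ridge(C, y, alpha=0.0)
        s = kpca.ridge_scores(m, np.array([[-1e-6], [1e-6]]))
        assert m.classes[s[0].argmax()] == "A"
        assert m.classes[s[1].argmax()] == "B"
        # at exactly 0 the class scores tie
        s0 = kpca.ridge_scores(m, np.array([[0.0]]))[0]
        assert s0[0] == pytest.approx(s0[1], abs=1e-9)

    def test_matches_sklearn_ridge_classifier(self):
        rng = np.random.default_rng(8)
        C = rng.normal(size=(40, 5))
        y = rng.integers(0, 3, size=40)
        ours = kpca.fit_ridge(C, y, alpha=1.0)
        sk = RidgeClassifier(alpha=1.0).fit(C, y)
        pred_ours = ours.classes[kpca.ridge_scores(ours, C).argmax(axis=1)]
        np.testing.assert_array_equal(pred_ours, sk.predict(C))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kpca.fit_ridge(np.zeros((4, 2)), np.array(["A"] * 4))


class TestPipeline:
    def _toy(self, n_per=15, seed=9):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.3, size=(n_per, 4)),
                       rng.normal(2.5, 0.3, size=(n_per, 4))])
        y = np.array(["A"] * n_per + ["B"] * n_per)
        return X, y

    def test_training_set_predictions_perfect_on_separable_toy(self):
        X, y = self._toy()
        res = kpca.KPCARidgeClassifier(X, y, gamma=0.5).fit()
        assert (res.predict(X) == y).all()
        assert res.train_accuracy == 1.0

    def test_full_pipeline_matches_naive_reference(self):
        """Naive reference: H K H eigensolver components + the same ridge;
        predictions must agree (signs cancel inside the linear classifier)."""
        X, y = self._toy(n_per=25, seed=10)
        res = kpca.KPCARidgeClassifier(X, y, gamma=0.5, n_components=10).fit()
        comps = naive_kpca_components(X, 0.5, 10)
        rmodel = kpca.fit_ridge(comps, y, alpha=1.0)
        pred_naive = rmodel.classes[kpca.ridge_scores(rmodel, comps).argmax(axis=1)]
        np.testing.assert_array_equal(res.predict(X), pred_naive)

    def test_prediction_invariant_to_duplicated_training_point(self):
        X, y = self._toy()
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        a = kpca.KPCARidgeClassifier(X, y, gamma=0.5).fit()
        b = kpca.KPCARidgeClassifier(Xd, yd, gamma=0.5).fit()
        probe = np.vstack([X - 0.05, X + 0.05])
        np.testing.assert_array_equal(a.predict(probe), b.predict(probe))

    def test_random_labels_large_alpha_near_chance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 4))
        y = np.repeat(["A", "B"], 50)
        res = kpca.KPCARidgeClassifier(X, y, gamma=0.5, alpha=1e9).fit()
        acc = res.score(rng.normal(size=(400, 4)), np.tile(np.repeat(["A", "B"], 1), 200))
        assert abs(acc - 0.5) < 0.1

    def test_gamma_grid_search_close_to_grid_maximum(self):
        rng = np.random.default_rng(12)

        def sample(n_per, seed):
            r = np.random.default_rng(seed)
            X = np.vstack([r.normal(0, 0.5, size=(n_per, 3)),
                           r.normal(1.5, 0.5, size=(n_per, 3))])
            return X, np.array(["A"] * n_per + ["B"] * n_per)

        Xtr, ytr = sample(30, 1)
        Xva, yva = sample(15, 2)
        Xte, yte = sample(40, 3)
        gammas = np.logspace(-3, 2, 6)
        best, _ = kpca.gamma_grid_search(Xtr, ytr, Xva, yva, gammas=gammas)
        test_by_gamma = {
            g: kpca.KPCARidgeClassifier(Xtr, ytr, gamma=float(g)).fit().score(Xte, yte)
            for g in gammas}
        assert test_by_gamma[best] >= max(test_by_gamma.values()) - 0.02
        del rng


class TestReduceTrainingSet:
    def test_sixteenth_of_1600_is_100(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(1600, 3))
        y = np.repeat(np.arange(8), 200)
        Xr, yr = kpca.reduce_training_set(X, y, 1 / 16, seed=0)
        assert len(yr) == 100

    def test_factor_one_is_identity(self):
        X = np.arange(12).reshape(6, 2)
        y = np.array([0, 0, 0, 1, 1, 1])
        Xr, yr = kpca.reduce_training_set(X, y, 1, seed=0)
        np.testing.assert_array_equal(Xr, X)

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(400, 2))
        y = np.repeat(np.arange(4), 100)
        _, yr = kpca.reduce_training_set(X, y, 0.25, seed=1)
        _, counts = np.unique(yr, return_counts=True)
        assert np.all(np.abs(counts - 25) <= 1)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            kpca.reduce_training_set(np.zeros((4, 2)), np.zeros(4), 0.5)


def test_time_grows_superlinearly_with_n():
    """Kernel + eigendecomposition cost: doubling n should far more than
    double the fit time (cubic eigensolve)."""
    rng = np.random.default_rng(15)
    X800 = rng.normal(size=(800, 30))
    X400 = X800[:400]

    def fit_time(X):
        best = np.inf
        for _ in range(2):
            t0 = time.perf_counter()
            kpca.fit_kpca(X, gamma=0.1, n_components=50)
            best = min(best, time.perf_counter() - t0)
        return best

    assert fit_time(X800) > 2.0 * fit_time(X400)
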