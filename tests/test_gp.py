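import numpy as np
import pytest

import gpconf as g
from gpconf.gp import LINEAR, kernel_matrix

SQEXP = g.KernelSpec("squared_exponential", length_scale=1.0)


def dense_reference(X, y, Xs, lam, spec):
    """Brute-force GP predictor and variance via plain dense linear algebra."""
    K = kernel_matrix(X, X, spec)
    L = kernel_matrix(X, Xs, spec)
    if spec.kind == "linear":
        M_diag = (Xs**2).sum(axis=1)
    else:
        M_diag = np.ones(len(Xs))
    A = K + lam * np.eye(len(X))
    alpha = np.linalg.solve(A, y)
    mean = L.T @ alpha
    var = M_diag - np.einsum("ij,ij->j", L, np.linalg.solve(A, L))
    return alpha, mean, var


class TestKernels:
    def test_linear_dot_product(self):
        assert g.kernel_eval([1, 2], [3, 4]) == 11

    def test_sqexp_unit_at_zero_distance(self):
        a = np.array([0.3, -1.2, 4.0])
        assert g.kernel_eval(a, a, SQEXP) == pytest.approx(1.0)

    def test_sqexp_closed_form(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])  # ||a-b|| = sqrt(2)
        assert g.kernel_eval(a, b, SQEXP) == pytest.approx(np.exp(-1.0))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=5)
        for spec in (LINEAR, SQEXP):
            assert g.kernel_eval(a, b, spec) == pytest.approx(g.kernel_eval(b, a, spec))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch|equal-length"):
            g.kernel_eval([1, 2], [1, 2, 3])

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            g.KernelSpec("cubic")
        with pytest.raises(ValueError):
            g.KernelSpec("squared_exponential")  # missing length scale


class TestFitPredict:
    def test_scalar_solve(self):
        m = g.fit(np.array([[1.0]]), np.array([2.0]), lam=0.0)
        np.testing.assert_allclose(m.alpha, [2.0])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("spec", [LINEAR, SQEXP], ids=["linear", "sqexp"])
    def test_matches_dense_reference(self, seed, spec):
        rng = np.random.default_rng(seed)
        n, d, m = rng.integers(5, 50), rng.integers(2, 20), 7
        X = rng.normal(size=(n, d))
        y = rng.normal(size=n)
        Xs = rng.normal(size=(m, d))
        # lambdas in the realistically selected range: smaller values on a
        # rank-deficient kernel leave the system too ill-conditioned for any
        # two correct solvers to agree tightly
        lam = 10.0 ** rng.integers(-2, 2)
        model = g.fit(X, y, lam, spec)
        alpha, mean, var = dense_reference(X, y, Xs, lam, spec)
        np.testing.assert_allclose(model.alpha, alpha, atol=1e-8)
        np.testing.assert_allclose(g.predict_mean(model, Xs), mean, atol=1e-8)
        np.testing.assert_allclose(g.predict_variance(model, Xs), np.clip(var, 0, None), atol=1e-8)

    def test_naive_kernel_sum_agreement(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(12, 3)), rng.normal(size=12)
        model = g.fit(X, y, 0.01)
        x_new = rng.normal(size=3)
        naive = sum(model.alpha[i] * g.kernel_eval(X[i], x_new) for i in range(12))
        assert g.predict_mean(model, x_new[None, :])[0] == pytest.approx(naive)

    def test_kernel_ridge_primal_dual_equivalence(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(30, 6)), rng.normal(size=30)
        Xs = rng.normal(size=(5, 6))
        lam = 0.1
        model = g.fit(X, y, lam)
        primal = Xs @ np.linalg.solve(X.T @ X + lam * np.eye(6), X.T @ y)
        np.testing.assert_allclose(g.predict_mean(model, Xs), primal, atol=1e-8)

    def test_ridge_shrinkage_monotone(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(20, 4)), rng.normal(size=20)
        norms = [np.linalg.norm(g.fit(X, y, lam).alpha) for lam in 2.0 ** np.arange(-4, 20)]
        assert np.all(np.diff(norms) < 0)

    def test_interpolates_training_data_at_zero_noise(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 6)) + 3 * np.eye(6)  # full rank
        y = rng.normal(size=6)
        model = g.fit(X, y, 0.0)
        np.testing.assert_allclose(g.predict_mean(model, X), y, atol=1e-6)
        np.testing.assert_allclose(g.predict_variance(model, X), 0, atol=1e-6)

    def test_empty_test_set(self):
        model = g.fit(np.eye(3), np.ones(3), 0.1)
        assert g.predict_mean(model, np.empty((0, 3))).shape == (0,)
        assert g.predict_variance(model, np.empty((0, 3))).shape == (0,)

    def test_dimension_mismatch_on_predict(self):
        model = g.fit(np.eye(3), np.ones(3), 0.1)
        with pytest.raises(ValueError, match="mismatch"):
            g.predict_mean(model, np.ones((2, 4)))

    def test_variance_bounded_by_prior(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(25, 4)), rng.normal(size=25)
        Xs = rng.normal(size=(40, 4))
        for spec in (LINEAR, SQEXP):
            model = g.fit(X, y, 0.5, spec)
            var = g.predict_variance(model, Xs)
            prior = (Xs**2).sum(1) if spec.kind == "linear" else np.ones(40)
            assert np.all(var <= prior + 1e-8)
            assert np.all(var >= 0)

    def test_variance_ignores_labels(self):
        rng = np.random.default_rng(6)
        X, y = rng.normal(size=(15, 3)), rng.normal(size=15)
        Xs = rng.normal(size=(8, 3))
        v1 = g.predict_variance(g.fit(X, y, 0.2), Xs)
        v2 = g.predict_variance(g.fit(X, rng.permutation(y), 0.2), Xs)
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_training_row_order_is_irrelevant(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        Xs = rng.normal(size=(6, 3))
        perm = rng.permutation(10)
        m1 = g.fit(X, y, 0.3)
        m2 = g.fit(X[perm], y[perm], 0.3)
        np.testing.assert_allclose(
            g.predict_mean(m2, Xs), g.predict_mean(m1, Xs), atol=1e-10
        )
        np.testing.assert_allclose(
            g.predict_variance(m2, Xs), g.predict_variance(m1, Xs), atol=1e-10
        )

    def test_centering_sets_y_center(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(10, 3)), rng.normal(5.0, 1.0, size=10)
        model = g.fit(X, y, 0.1, center=True)
        assert model.y_center == pytest.approx(y.mean())
        # the zero descriptor predicts the training mean under the linear kernel
        assert g.predict_mean(model, np.zeros((1, 3)))[0] == pytest.approx(y.mean())

    def test_model_consistency_invariant(self):
        rng = np.random.default_rng(9)
        X, y = rng.normal(size=(12, 4)), rng.normal(size=12)
        model = g.fit(X, y, 0.05)
        K = kernel_matrix(X, X, LINEAR)
        lhs = (K + model.lam * np.eye(12)) @ model.alpha
        np.testing.assert_allclose(lhs, y, rtol=1e-8)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        Xs = rng.normal(size=(4, 3))
        model = g.fit(X, y, 0.2)
        g.save_model(model, tmp_path / "m.npz")
        loaded = g.load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(g.predict_mean(loaded, Xs), g.predict_mean(model, Xs))
        np.testing.assert_allclose(
            g.predict_variance(loaded, Xs), g.predict_variance(model, Xs), atol=1e-10
        )


class TestSelectNoise:
    def test_single_value_grid(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        lam, table = g.select_noise(X, y, grid=np.array([0.5]), k=5)
        assert lam == 0.5
        assert len(table) == 1

    def test_noise_free_linear_data_picks_grid_minimum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        lam, _ = g.select_noise(X, y, k=5)
        assert lam == g.DEFAULT_LAMBDA_GRID[0]

    def test_chosen_lambda_near_fine_grid_optimum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        y = X @ rng.normal(size=5) + rng.normal(0, 1.0, size=80)
        coarse, _ = g.select_noise(X, y, k=5, seed=0)
        fine_grid = np.logspace(-8, 4, 97)
        fine, _ = g.select_noise(X, y, grid=fine_grid, k=5, seed=0)
        # within two coarse grid steps (factor 100) of the fine-grid optimum
        assert abs(np.log10(coarse) - np.log10(fine)) <= 2.0 + 1e-9

    @pytest.mark.parametrize("shape", [(40, 6), (15, 30)], ids=["tall-primal", "wide-dual"])
    def test_cv_table_matches_explicit_refits(self, shape):
        """The fast grid-search inner loop (primal for tall data, eigh otherwise)
        must reproduce a plain fit/predict loop fold by fold."""
        from gpconf.gp import _cv_mae_table
        from gpconf.validation import stratified_folds

        rng = np.random.default_rng(3)
        n, d = shape
        X = rng.normal(size=(n, d))
        y = X @ rng.normal(size=d) + rng.normal(0, 0.5, n)
        grid = np.logspace(-6, 2, 5)
        k = 5
        folds = stratified_folds(y, k, seed=0)
        fast = _cv_mae_table(X, y, grid, LINEAR, folds.fold_of, k)
        slow = np.zeros((k, len(grid)))
        for f in range(k):
            te = folds.fold_of == f
            for j, lam in enumerate(grid):
                model = g.fit(X[~te], y[~te], lam, with_train_variance=False)
                slow[f, j] = np.abs(g.predict_mean(model, X[te]) - y[te]).mean()
        np.testing.assert_allclose(fast, slow.mean(axis=0), rtol=1e-7, atol=1e-10)

    def test_rejects_bad_grids(self):
        X, y = np.eye(12), np.ones(12)
        with pytest.raises(ValueError, match="increasing"):
            g.select_noise(X, y, grid=np.array([1.0, 0.5]), k=3)
        with pytest.raises(ValueError, match="positive"):
            g.select_noise(X, y, grid=np.array([-1.0, 1.0]), k=3)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="smaller k"):
            g.select_noise(np.eye(5), np.ones(5), k=10)
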