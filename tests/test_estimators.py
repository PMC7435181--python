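import numpy as np
import pytest

from angulai.estimators import (
    fit_linear,
    fit_plsr,
    kfold_indices,
    plsr_loadings,
    select_components,
    train_bpnn,
)


class TestFitLinear:
    def test_two_point_line(self):
        m = fit_linear([0, 1], [1, 3])
        assert (m.slope, m.intercept) == (2.0, 1.0)

    def test_perfect_fit(self):
        x = np.arange(10.0)
        m = fit_linear(x, x)
        np.testing.assert_allclose(m.predict(x), x, atol=1e-12)

    def test_closed_form_oracle(self):
        m = fit_linear([0, 1, 2], [0, 1, 3])
        assert m.slope == pytest.approx(1.5, abs=1e-12)
        assert m.intercept == pytest.approx(-1 / 6, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([2, 2, 2], [1, 2, 3])


class TestPLSR:
    def test_single_predictor_collapses_to_ols(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2.5 * x[:, 0] + 1 + rng.normal(0, 0.1, 30)
        model = fit_plsr(x, y, A=1)
        lm = fit_linear(x[:, 0], y)
        np.testing.assert_allclose(model.predict(x), lm.predict(x[:, 0]), atol=1e-10)

    def test_full_rank_equals_multivariate_ols(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = fit_plsr(X, y, A=4)
        A = np.column_stack([X, np.ones(10)])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), A @ coef, atol=1e-8)

    def test_perfect_collinearity(self, rng):
        # y duplicated as a column; distractor columns are orthogonalized
        # against y so the first weight vector aligns exactly with it
        y = rng.normal(size=25)
        D = rng.normal(size=(25, 3))
        yc = y - y.mean()
        D = D - np.outer(yc, yc @ (D - D.mean(axis=0))) / (yc @ yc)
        X = np.column_stack([y, D])
        model = fit_plsr(X, y, A=1)
        resid = y - model.predict(X)
        sst = ((y - y.mean()) ** 2).sum()
        assert 1 - (resid**2).sum() / sst > 1 - 1e-10

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        model = fit_plsr(X, y, A=8)
        T = model.scores(X)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_two_prediction_paths_agree(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, A=5)
        Xnew = rng.normal(size=(7, 20))
        np.testing.assert_allclose(
            model.predict(Xnew), model.predict_sequential(Xnew), atol=1e-10
        )

    def test_matches_sklearn_reference(self, rng):
        # independent cross-check against an established implementation
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(40, 25))
        y = rng.normal(size=40) + X[:, :3] @ np.array([1.0, -2.0, 0.5])
        model = fit_plsr(X, y, A=4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.predict(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_invalid_arguments(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit_plsr(X, np.full(10, 2.0), A=2)  # zero-variance y
        with pytest.raises(ValueError):
            fit_plsr(X, rng.normal(size=10), A=10)  # A > min(n-1, p)

    def test_loadings_shape_and_range(self, rng):
        X = rng.normal(size=(30, 501))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, A=3)
        assert plsr_loadings(model, 1).shape == (501,)
        with pytest.raises(IndexError):
            plsr_loadings(model, 4)

    def test_rank_one_loading_matches_svd(self, rng):
        # on rank-1 X the first loading must align with the singular vector
        u = rng.normal(size=20)
        v = rng.normal(size=8)
        X = np.outer(u, v)
        y = u * 2.0
        model = fit_plsr(X, y, A=1)
        _, _, Vt = np.linalg.svd(X - X.mean(axis=0))
        p1 = plsr_loadings(model, 1)
        cos = abs(p1 @ Vt[0]) / (np.linalg.norm(p1) * np.linalg.norm(Vt[0]))
        assert cos == pytest.approx(1.0, abs=1e-8)


class TestSelectComponents:
    def test_three_factor_recovery(self):
        rng = np.random.default_rng(2024)
        n, p = 80, 60
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, p))
        X = T @ P + 0.05 * rng.normal(size=(n, p))
        y = T @ np.array([1.0, -1.5, 0.8]) + 0.1 * rng.normal(size=n)
        sel = select_components(X, y, A_max=10, seed=0)
        assert sel.chosen in (3, 4)

    def test_single_candidate(self, rng):
        X = rng.normal(size=(20, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        sel = select_components(X, y, A_max=1, seed=1)
        assert sel.chosen == 1 and len(sel.cv_rmse) == 1

    def test_curve_length_matches_a_max(self, rng):
        X = rng.normal(size=(40, 30))
        y = rng.normal(size=40)
        sel = select_components(X, y, A_max=7, seed=2)
        assert len(sel.cv_rmse) == 7 and sel.candidates == list(range(1, 8))

    def test_chosen_attains_minimum(self, rng):
        X = rng.normal(size=(50, 20))
        y = X[:, 0] - X[:, 3] + rng.normal(0, 0.3, 50)
        sel = select_components(X, y, A_max=8, seed=3)
        assert sel.cv_rmse[sel.chosen - 1] == sel.cv_rmse.min()


class TestKFold:
    def test_near_equal_sizes_and_coverage(self):
        folds = kfold_indices(176, 5, seed=0)
        sizes = sorted(np.bincount(folds)[1:])
        assert sizes == [35, 35, 35, 35, 36]
        assert set(folds) == {1, 2, 3, 4, 5}


class TestBPNN:
    def test_recovers_linear_signal(self, rng):
        n, p = 120, 15
        X = rng.normal(size=(n, p))
        w = rng.normal(size=p)
        y = X @ w + rng.normal(0, 0.1, n)
        tr = slice(0, 90)
        te = slice(90, None)
        model, _ = train_bpnn(
            X[tr], y[tr], hidden_grid=(5, 20), repeats=3, epochs=1000, seed=0
        )
        pred = model.predict(X[te])
        sst = ((y[te] - y[te].mean()) ** 2).sum()
        r2 = 1 - ((y[te] - pred) ** 2).sum() / sst
        assert r2 >= 0.9

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 10))
        y = X[:, 0] + rng.normal(0, 0.2, 50)
        m1, _ = train_bpnn(X, y, hidden_grid=(5,), repeats=2, epochs=50, seed=5)
        m2, _ = train_bpnn(X, y, hidden_grid=(5,), repeats=2, epochs=50, seed=5)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_degenerate_grid_single_candidate(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 1] + rng.normal(0, 0.1, 40)
        _, report = train_bpnn(X, y, hidden_grid=(5,), repeats=1, epochs=50, seed=0)
        assert report.hidden_grid == [5] and len(report.cv_rmse_by_hidden) == 1

    def test_predictions_always_finite(self, rng):
        X = rng.uniform(0, 1, size=(60, 12))
        y = 3 * X[:, 0] + rng.normal(0, 0.1, 60)
        model, _ = train_bpnn(X, y, hidden_grid=(10,), repeats=1, epochs=100, seed=2)
        assert np.isfinite(model.predict(rng.uniform(0, 1, size=(30, 12)))).all()

    def test_out_of_range_hidden_rejected(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            train_bpnn(X, y, hidden_grid=(3,), repeats=1)
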