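"""NIPALS PLS1 against independent oracles, plus its algebraic identities."""

import numpy as np
import pytest

from nichepls.pls import PLSModel, explained_variance, fit_nipals, predict, vip_scores

from .conftest import random_scaled_dm


def oracle_pls1(X, y, n_components):
    """Independent PLS1: weights from the leading eigenvector of X'yy'X.

    Returns per-component (w, t, p, q). Deliberately written in a different
    formulation (dense eigendecomposition of the rank-one covariance operator)
    from the production NIPALS loop.
    """
    X = X.copy().astype(float)
    y = np.asarray(y, dtype=float)
    out = []
    for _ in range(n_components):
        M = np.outer(X.T @ y, X.T @ y)
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, np.argmax(vals)]
        if w @ (X.T @ y) < 0:  # orient along the covariance direction
            w = -w
        t = X @ w
        tt = t @ t
        p = X.T @ t / tt
        q = (y @ t) / tt
        X = X - np.outer(t, p)
        out.append((w, t, p, q))
    return out


def oracle_predictions(X, y, n_components):
    comps = oracle_pls1(X, y, n_components)
    W = np.column_stack([c[0] for c in comps])
    P = np.column_stack([c[2] for c in comps])
    q = np.array([c[3] for c in comps])
    return X @ (W @ np.linalg.solve(P.T @ W, q))


class TestFitAgainstOracles:
    def test_predictions_match_eigenvector_oracle(self):
        dm = random_scaled_dm(n=8, p=5, seed=11, noise=0.5)
        model = fit_nipals(dm, 2)
        yhat = dm.y_mean + dm.y_sd * (dm.X @ model.coeff_scaled)
        expected = dm.y_mean + dm.y_sd * oracle_predictions(dm.X, dm.y, 2)
        np.testing.assert_allclose(yhat, expected, atol=1e-8)

    def test_predictions_match_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        dm = random_scaled_dm(n=12, p=5, seed=4, noise=0.3)
        for A in (1, 2, 3):
            model = fit_nipals(dm, A)
            ours = dm.y_mean + dm.y_sd * (dm.X @ model.coeff_scaled)
            ref = sklearn.PLSRegression(n_components=A, scale=False)
            ref.fit(dm.X, dm.y)
            np.testing.assert_allclose(ours, dm.y_mean + dm.y_sd * ref.predict(dm.X).ravel(),
                                       atol=1e-8)

    def test_full_components_reach_least_squares(self):
        dm = random_scaled_dm(n=10, p=4, seed=7, noise=0.4)
        model = fit_nipals(dm, 4)
        b_ls, *_ = np.linalg.lstsq(dm.X, dm.y, rcond=None)
        np.testing.assert_allclose(dm.X @ model.coeff_scaled, dm.X @ b_ls, atol=1e-8)

    def test_single_collinear_column(self):
        dm = random_scaled_dm(n=9, p=1, seed=2, beta=[2.0], noise=0.0)
        model = fit_nipals(dm, 1)
        assert model.explained_y[-1] == pytest.approx(1.0, abs=1e-12)
        assert model.coeff_scaled[0] == pytest.approx(1.0, abs=1e-12)  # corr sign & unit SD

    def test_one_predictor_equals_simple_regression(self):
        from .conftest import random_unscaled_dm
        from nichepls.design import center_scale

        dm = random_unscaled_dm(n=15, p=1, seed=9, noise=0.5)
        model = fit_nipals(center_scale(dm), 1)
        slope, intercept = np.polyfit(dm.X[:, 0], dm.y, 1)
        assert model.coeff_raw[0] == pytest.approx(slope, rel=1e-10)
        assert model.intercept_raw == pytest.approx(intercept, rel=1e-10)

    def test_too_many_components_rejected(self):
        dm = random_scaled_dm(n=6, p=3, seed=0, noise=0.2)
        with pytest.raises(ValueError, match="rank"):
            fit_nipals(dm, 5)

    def test_early_stop_when_no_covariance_left(self):
        # X has two orthogonal directions but y lives entirely in the first:
        # after one deflation no covariance remains, the second component is skipped
        dm = random_scaled_dm(n=8, p=2, seed=5, noise=0.0)
        Q, _ = np.linalg.qr(dm.X - dm.X.mean(axis=0))
        dm.X = Q
        dm.y = Q[:, 0].copy()
        with pytest.warns(UserWarning, match="stopping early"):
            model = fit_nipals(dm, 2)
        assert model.n_components == 1


class TestPredict:
    def test_training_round_trip(self):
        from .conftest import random_unscaled_dm
        from nichepls.design import center_scale

        dm = random_unscaled_dm(n=12, p=4, seed=3, noise=0.3)
        scaled = center_scale(dm)
        model = fit_nipals(scaled, 2)
        yhat = predict(model, dm.X, column_names=dm.column_names)
        expected = scaled.y_mean + scaled.y_sd * (scaled.X @ model.coeff_scaled)
        np.testing.assert_allclose(yhat, expected, atol=1e-10)

    def test_row_of_column_means_predicts_response_mean(self):
        from .conftest import random_unscaled_dm
        from nichepls.design import center_scale

        dm = random_unscaled_dm(n=12, p=4, seed=8, noise=0.3)
        model = fit_nipals(center_scale(dm), 2)
        yhat = predict(model, dm.X.mean(axis=0), column_names=dm.column_names)
        assert yhat[0] == pytest.approx(dm.y.mean())

    def test_one_component_closed_form(self):
        # hand-built: yhat = ybar + sd(y) * q * t for a single component
        from .conftest import random_unscaled_dm
        from nichepls.design import center_scale

        dm = random_unscaled_dm(n=7, p=3, seed=13, noise=0.2)
        scaled = center_scale(dm)
        model = fit_nipals(scaled, 1)
        c = scaled.X.T @ scaled.y
        w = c / np.linalg.norm(c)
        t = scaled.X @ w
        q = (scaled.y @ t) / (t @ t)
        # b = w * q / (p'w); for one component W(P'W)^-1 q reduces to this
        p_load = scaled.X.T @ t / (t @ t)
        expected = scaled.y_mean + scaled.y_sd * (scaled.X @ (w * q / (p_load @ w)))
        yhat = predict(model, dm.X, column_names=dm.column_names)
        np.testing.assert_allclose(yhat, expected, atol=1e-10)

    def test_missing_column_named_in_error(self):
        import pandas as pd

        dm = random_scaled_dm(n=8, p=3, seed=1, noise=0.2)
        model = fit_nipals(dm, 1)
        rows = pd.DataFrame({"x0": [0.0], "x1": [0.0]})
        with pytest.raises(KeyError, match="x2"):
            predict(model, rows)

    def test_extra_columns_ignored_by_name(self):
        import pandas as pd

        dm = random_scaled_dm(n=8, p=3, seed=1, noise=0.2)
        model = fit_nipals(dm, 1)
        rows = pd.DataFrame(dm.X, columns=dm.column_names)
        rows["irrelevant"] = 99.0
        shuffled = rows[["irrelevant", "x2", "x0", "x1"]]
        np.testing.assert_allclose(
            predict(model, shuffled), predict(model, dm.X, column_names=dm.column_names)
        )


class TestVIP:
    def test_brute_force_formula(self):
        dm = random_scaled_dm(n=8, p=5, seed=21, noise=0.5)
        model = fit_nipals(dm, 2)
        p = dm.n_columns
        ssy = [model.q[a] ** 2 * model.t_norms[a] for a in range(2)]
        expected = np.empty(p)
        for j in range(p):  # term-by-term, loop-based evaluation
            num = sum(ssy[a] * (model.W[j, a] / np.linalg.norm(model.W[:, a])) ** 2
                      for a in range(2))
            expected[j] = np.sqrt(p * num / sum(ssy))
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-12)

    def test_equal_weights_give_unit_vip(self):
        n, p = 40, 4
        rng = np.random.default_rng(0)
        z = rng.normal(size=n)
        X = np.tile(z[:, None], (1, p)) + rng.normal(scale=1e-9, size=(n, p))
        from nichepls.design import DesignMatrix, EncodingConfig, center_scale

        dm = center_scale(DesignMatrix([f"s{i}" for i in range(n)],
                                       [f"x{j}" for j in range(p)],
                                       X, z + rng.normal(scale=0.1, size=n),
                                       [("G", "G")] * n, EncodingConfig()))
        model = fit_nipals(dm, 1)
        np.testing.assert_allclose(model.vip, np.ones(p), atol=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_square_is_one(self, seed):
        dm = random_scaled_dm(n=10, p=6, seed=seed, noise=0.7)
        model = fit_nipals(dm, 3)
        assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-10)


class TestExplainedVariance:
    def test_rank_one_everything_at_first_component(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=10)
        v = rng.normal(size=4)
        from nichepls.design import DesignMatrix, EncodingConfig, center_scale

        dm = center_scale(DesignMatrix([f"s{i}" for i in range(10)],
                                       [f"x{j}" for j in range(4)],
                                       np.outer(u, v), 3.0 * u,
                                       [("G", "G")] * 10, EncodingConfig()))
        model = fit_nipals(dm, 1)
        ex, ey = explained_variance(model)
        assert ex[0] == pytest.approx(1.0, abs=1e-10)
        assert ey[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_rank_explains_all_x(self):
        dm = random_scaled_dm(n=10, p=4, seed=17, noise=0.5)
        model = fit_nipals(dm, 4)
        assert model.explained_x[-1] == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_deflation_fractions(self):
        dm = random_scaled_dm(n=6, p=3, seed=23, noise=0.4)
        model = fit_nipals(dm, 2)
        X = dm.X.copy()
        total = (X**2).sum()
        fractions = []
        Xd = X.copy()
        for a in range(2):
            t = Xd @ model.W[:, a]
            Xd = Xd - np.outer(t, Xd.T @ t / (t @ t))
            fractions.append(1 - (Xd**2).sum() / total)
        np.testing.assert_allclose(model.explained_x, fractions, atol=1e-10)

    def test_monotone_and_bounded(self):
        dm = random_scaled_dm(n=12, p=6, seed=29, noise=0.8)
        model = fit_nipals(dm, 5)
        for arr in (model.explained_x, model.explained_y):
            assert (np.diff(arr) >= -1e-12).all()
            assert (arr <= 1 + 1e-12).all()


class TestStructure:
    def test_scores_orthogonal(self):
        dm = random_scaled_dm(n=12, p=6, seed=31, noise=0.6)
        model = fit_nipals(dm, 4)
        G = model.T.T @ model.T
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_permutation_equivariance(self):
        dm = random_scaled_dm(n=10, p=5, seed=37, noise=0.5)
        model = fit_nipals(dm, 2)
        perm = [3, 0, 4, 1, 2]
        dm2 = random_scaled_dm(n=10, p=5, seed=37, noise=0.5)
        dm2.X = dm2.X[:, perm]
        dm2.column_names = [dm.column_names[j] for j in perm]
        dm2.column_means = dm2.column_means[perm]
        dm2.column_sds = dm2.column_sds[perm]
        model2 = fit_nipals(dm2, 2)
        np.testing.assert_allclose(model2.coeff_scaled, model.coeff_scaled[perm], atol=1e-12)
        np.testing.assert_allclose(model2.vip, model.vip[perm], atol=1e-12)

    def test_weight_sign_convention(self):
        for seed in range(5):
            dm = random_scaled_dm(n=9, p=4, seed=seed, noise=0.5)
            model = fit_nipals(dm, 2)
            for a in range(model.n_components):
                w = model.W[:, a]
                first = w[np.flatnonzero(np.abs(w) > 1e-14)[0]]
                assert first > 0

    def test_serialization_round_trip(self, tmp_path):
        dm = random_scaled_dm(n=10, p=4, seed=41, noise=0.3)
        model = fit_nipals(dm, 2)
        path = tmp_path / "model.json"
        model.save(path)
        back = PLSModel.load(path)
        X_raw = dm.X * dm.column_sds + dm.column_means
        np.testing.assert_allclose(
            predict(back, X_raw, column_names=dm.column_names),
            predict(model, X_raw, column_names=dm.column_names),
        )
        np.testing.assert_array_equal(back.vip, model.vip)
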