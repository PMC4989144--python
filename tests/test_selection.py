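"""Cross-validated component selection, the Van der Voet test, and VIP pruning."""

import numpy as np
import pytest

from nichepls.design import DesignMatrix, EncodingConfig, center_scale
from nichepls.pls import fit_nipals
from nichepls.selection import (
    choose_components,
    kfold_press,
    prune_and_refit,
    select_model,
    van_der_voet_test,
)

from .conftest import random_unscaled_dm


def _dm(X, y, names=None):
    n, p = X.shape
    return DesignMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        column_names=names or [f"x{j}" for j in range(p)],
        X=np.asarray(X, dtype=float),
        y=np.asarray(y, dtype=float),
        groups=[("G", "G")] * n,
        encoding=EncodingConfig(),
    )


class TestKFoldPress:
    def test_leave_one_out_matches_brute_force(self):
        # 5x2 toy, every fold re-derived from first principles in this test
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 2))
        y = X @ np.array([1.5, -0.7]) + rng.normal(scale=0.3, size=5)
        dm = _dm(X, y)
        press, resid, press_null, _ = kfold_press(dm, max_components=1, k=5, seed=0)

        sd_global = y.std(ddof=1)
        total = 0.0
        for i in range(5):
            tr = [j for j in range(5) if j != i]
            Xt, yt = X[tr], y[tr]
            mx, sx = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
            my, sy = yt.mean(), yt.std(ddof=1)
            Xs, ys = (Xt - mx) / sx, (yt - my) / sy
            c = Xs.T @ ys
            w = c / np.linalg.norm(c)
            t = Xs @ w
            q = (ys @ t) / (t @ t)
            p_load = Xs.T @ t / (t @ t)
            b = w * q / (p_load @ w)  # 1-component coefficients
            pred = my + sy * (((X[i] - mx) / sx) @ b)
            total += ((y[i] - pred) / sd_global) ** 2
        assert press[0] == pytest.approx(total, rel=1e-10)

    def test_same_seed_is_deterministic(self):
        dm = random_unscaled_dm(n=14, p=4, seed=2, noise=0.5)
        a = kfold_press(dm, 3, k=4, seed=9)
        b = kfold_press(dm, 3, k=4, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_noiseless_rank_one_optimum_at_one_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=12)
        v = rng.normal(size=3)
        X = np.outer(u, v) + rng.normal(scale=1e-8, size=(12, 3))
        y = 2.0 * u
        press, *_ = kfold_press(_dm(X, y), max_components=2, k=4, seed=0)
        assert np.argmin(press) == 0

    def test_chosen_model_beats_null_press(self):
        dm = random_unscaled_dm(n=20, p=4, seed=3, noise=0.3)
        press, _, press_null, _ = kfold_press(dm, 4, k=5, seed=1)
        assert press.min() <= press_null

    def test_k_bounds_validated(self):
        dm = random_unscaled_dm(n=6, p=2, seed=0)
        with pytest.raises(ValueError):
            kfold_press(dm, 1, k=1, seed=0)
        with pytest.raises(ValueError):
            kfold_press(dm, 1, k=7, seed=0)

    def test_stratified_folds_spread_groups(self):
        groups = [("A", "1")] * 8 + [("B", "2")] * 8
        dm = random_unscaled_dm(n=16, p=2, seed=4, noise=0.2, groups=groups)
        from nichepls.selection import _fold_assignment

        folds = _fold_assignment(dm, 4, seed=0)
        for f in range(4):
            labels = {groups[i] for i in np.flatnonzero(folds == f)}
            assert len(labels) == 2  # every fold sees both condition groups


class TestVanDerVoet:
    def test_identical_residuals_give_p_one(self):
        e = np.array([0.3, -0.2, 0.5, 0.1])
        assert van_der_voet_test(e, e.copy()) == 1.0

    def test_exhaustive_enumeration_matches_library_path(self):
        # small n: the library enumerates all sign flips; reproduce that here
        # from scratch and compare
        rng = np.random.default_rng(7)
        e_c = rng.normal(size=8) * 1.4
        e_o = rng.normal(size=8)
        d = e_c**2 - e_o**2
        count = 0
        for mask in range(2**8):  # deliberately naive loop
            T = sum((1 if mask >> i & 1 else -1) * d[i] for i in range(8))
            count += abs(T) >= abs(d.sum()) - 1e-12
        assert van_der_voet_test(e_c, e_o) == pytest.approx(count / 2**8)

    def test_sampled_p_matches_exhaustive_within_monte_carlo_error(self):
        rng = np.random.default_rng(8)
        e_c = rng.normal(size=16) * 1.3
        e_o = rng.normal(size=16)
        d = e_c**2 - e_o**2
        signs = ((np.arange(2**16)[:, None] >> np.arange(16)) & 1) * 2 - 1
        p_ref = (np.abs(signs @ d) >= abs(d.sum()) - 1e-12).mean()
        p_s = van_der_voet_test(e_c, e_o, n_perm=100_000, seed=3)
        assert p_s == pytest.approx(p_ref, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            van_der_voet_test(np.ones(4), np.ones(5))

    def test_type_one_error_calibrated(self):
        # both residual vectors from the same symmetric law: p <= 0.10 should
        # occur at about the nominal rate (binomial 99% band around 0.10)
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            e_c = rng.normal(size=10)
            e_o = rng.normal(size=10)
            if van_der_voet_test(e_c, e_o) <= 0.10:
                rejections += 1
        rate = rejections / n_rep
        half = 2.576 * np.sqrt(0.1 * 0.9 / n_rep)
        assert 0.10 - half <= rate <= 0.10 + half

    def test_p_values_super_uniform_under_null(self):
        rng = np.random.default_rng(11)
        pvals = np.array([
            van_der_voet_test(rng.normal(size=10), rng.normal(size=10))
            for _ in range(400)
        ])
        for alpha in (0.05, 0.2, 0.5):
            assert (pvals <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 400)


class TestChooseComponents:
    def test_rule_application(self):
        chosen, fallback = choose_components(
            press=[5.0, 2.0, 1.0],
            van_der_voet_p=[0.02, 0.5, 1.0],
            explained_x=[0.95, 0.97, 0.99],
            explained_y=[0.5, 0.92, 0.99],
            alpha=0.10,
        )
        assert (chosen, fallback) == (2, False)

    def test_fallback_to_press_optimum(self):
        chosen, fallback = choose_components(
            press=[5.0, 1.0, 2.0],
            van_der_voet_p=[0.01, 1.0, 0.8],
            explained_x=[0.5, 0.6, 0.7],  # variance rule never met
            explained_y=[0.9, 0.95, 0.99],
        )
        assert (chosen, fallback) == (2, True)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            choose_components([], [], [], [])

    def test_three_latent_factor_recovery(self):
        # X carries exactly 3 latent directions, each needed to predict y:
        # the selection should land on 3 components in nearly every replicate
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            T, _ = np.linalg.qr(rng.normal(size=(36, 3)))
            P = rng.normal(size=(8, 3))
            X = T @ P.T + rng.normal(scale=1e-2, size=(36, 8))
            y = T @ np.array([3.0, 2.0, 1.5]) + rng.normal(scale=0.1, size=36)
            _, _, report = select_model(_dm(X, y), k=6, n_perm=300, seed=seed,
                                        max_components=6)
            hits += report.chosen_components == 3
        assert hits / n_rep >= 0.9


class TestPruneAndRefit:
    def test_noop_when_all_vips_above_threshold(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=20)
        X = np.column_stack([z, -z]) + rng.normal(scale=1e-6, size=(20, 2))
        y = z + rng.normal(scale=0.05, size=20)
        dm = _dm(X, y)
        model, _, _ = select_model(dm, k=4, n_perm=200, seed=0)
        assert (model.vip >= 0.8).all()
        reduced_dm, reduced_model, report = prune_and_refit(
            dm, model, k=4, n_perm=200, seed=0
        )
        assert reduced_model.column_names == model.column_names
        assert report.kept_variables == model.column_names

    def test_default_threshold(self):
        import inspect

        assert inspect.signature(prune_and_refit).parameters["vip_threshold"].default == 0.8

    def test_all_pruned_raises(self):
        dm = random_unscaled_dm(n=12, p=3, seed=6, noise=0.4)
        model, _, _ = select_model(dm, k=4, n_perm=200, seed=0)
        with pytest.raises(ValueError, match="prunes every variable"):
            prune_and_refit(dm, model, vip_threshold=10.0, k=4, n_perm=200, seed=0)

    def test_informative_kept_noise_pruned(self):
        # 4 informative + 10 pure-noise predictors at low noise
        kept_informative = 0
        pruned_noise = 0
        total_noise = 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 14))
            beta = np.zeros(14)
            beta[:4] = [2.0, -2.0, 1.6, -1.6]
            y = X @ beta + rng.normal(scale=0.4, size=40)
            dm = _dm(X, y)
            model, _, _ = select_model(dm, k=5, n_perm=200, seed=seed)
            _, reduced, report = prune_and_refit(dm, model, k=5, n_perm=200, seed=seed)
            kept = set(report.kept_variables)
            kept_informative += sum(f"x{j}" in kept for j in range(4))
            pruned_noise += sum(f"x{j}" not in kept for j in range(4, 14))
            total_noise += 10
        assert kept_informative == 4 * n_rep
        assert pruned_noise / total_noise >= 0.7


def test_selection_is_pure_function_of_inputs():
    dm = random_unscaled_dm(n=18, p=5, seed=12, noise=0.4)
    m1, _, r1 = select_model(dm, k=5, n_perm=500, seed=77)
    m2, _, r2 = select_model(dm, k=5, n_perm=500, seed=77)
    np.testing.assert_array_equal(m1.coeff_scaled, m2.coeff_scaled)
    assert r1.to_dict() == r2.to_dict()
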