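"""Penalized solver: objective, prox, fits, path, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from scggm.model import CGGMModel, SufficientStats
from scggm.optim import (
    FitOptions,
    cross_validate,
    fit_from_stats,
    fit_path,
    fit_scggm,
    kkt_violation,
    objective,
    prox_l1,
)
from scggm.inference import indirect_effects
from scggm.evaluate import prediction_error
from scggm.simulate import simulate_cggm_dataset

from .conftest import random_model, random_stats
from .oracles import active_set_solve


class TestObjective:
    def test_zero_penalties_equal_nll(self, rng):
        from scggm.model import neg_log_likelihood

        m = random_model(4, 3, rng)
        stats = random_stats(4, 3, 20, rng)
        assert objective(m, stats, 0.0, 0.0) == pytest.approx(
            neg_log_likelihood(m, stats), abs=1e-14)

    def test_diagonal_unpenalized(self, rng):
        stats = random_stats(3, 2, 20, rng)
        m = CGGMModel(Lambda=np.eye(3), Theta=np.zeros((2, 3)))
        from scggm.model import neg_log_likelihood

        assert objective(m, stats, 5.0, 7.0) == pytest.approx(
            neg_log_likelihood(m, stats), abs=1e-14)

    def test_penalty_arithmetic(self, rng):
        from scggm.model import neg_log_likelihood

        m = random_model(4, 3, rng)
        stats = random_stats(4, 3, 20, rng)
        ln, lp = 0.3, 0.7
        off = np.abs(m.Lambda).sum() - np.abs(np.diag(m.Lambda)).sum()
        expected = ln * off + lp * np.abs(m.Theta).sum()
        got = objective(m, stats, ln, lp) - neg_log_likelihood(m, stats)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_negative_penalty_rejected(self, rng):
        m = random_model(2, 1, rng)
        stats = random_stats(2, 1, 10, rng)
        with pytest.raises(ValueError):
            objective(m, stats, -0.1, 0.0)


class TestProxL1:
    def test_hand_computed(self):
        M = np.array([[3.0, -2.0], [0.5, 1.0]])
        np.testing.assert_array_equal(
            prox_l1(M, 1.0), np.array([[2.0, -1.0], [0.0, 0.0]]))

    def test_zero_threshold_identity(self, rng):
        M = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(prox_l1(M, 0.0), M)

    def test_skip_diagonal_preserves_diagonal_matrix(self):
        M = np.diag([3.0, -0.2, 1.0])
        np.testing.assert_array_equal(prox_l1(M, 10.0, skip_diagonal=True), M)

    @settings(deadline=None, max_examples=50)
    @given(
        M=arrays(np.float64, (3, 3), elements=st.floats(-10, 10)),
        t=st.floats(0, 5),
    )
    def test_shrinks_toward_zero_and_never_flips_sign(self, M, t):
        out = prox_l1(M, t)
        assert np.all(np.abs(out) <= np.abs(M) + 1e-12)
        assert np.all(out * M >= 0)


class TestFit:
    def test_consistency_large_n_small_penalty(self, rng):
        """At large n and tiny penalties the estimate approaches the truth."""
        p, q, n = 3, 2, 2000
        Lam = np.array([[1.5, -0.4, 0.0], [-0.4, 1.2, -0.3], [0.0, -0.3, 1.0]])
        Theta = np.array([[0.8, 0.0, 0.0], [0.0, -0.6, 0.0]])
        X = rng.standard_normal((n, q))
        X = (X - X.mean(0)) / X.std(0)
        B = -Theta @ np.linalg.inv(Lam)
        L = np.linalg.cholesky(Lam)
        noise = np.linalg.solve(L.T, rng.standard_normal((n, p)).T).T
        Y = X @ B + noise
        Y -= Y.mean(0)
        stats = SufficientStats.from_arrays(X, Y)
        m = fit_from_stats(stats, 1e-3, 1e-3, FitOptions(tol=1e-9, max_iter=10000))
        assert np.max(np.abs(m.Lambda - Lam)) < 0.1
        assert np.max(np.abs(m.Theta - Theta)) < 0.1

    def test_matches_reference_solver(self, rng):
        """Proximal-gradient solution vs the independent active-set solver."""
        p, q, n = 4, 3, 50
        stats = random_stats(p, q, n, rng)
        m = fit_from_stats(stats, 0.1, 0.1, FitOptions(tol=1e-11, max_iter=50000))
        Lam_o, Th_o = active_set_solve(stats, 0.1, 0.1)
        f_fit = objective(m, stats, 0.1, 0.1)
        f_ref = objective(CGGMModel(Lambda=Lam_o, Theta=Th_o), stats, 0.1, 0.1)
        assert f_fit <= f_ref + 1e-4
        assert np.max(np.abs(m.Lambda - Lam_o)) < 1e-3
        assert np.max(np.abs(m.Theta - Th_o)) < 1e-3

    def test_kkt_optimality_at_solution(self, rng):
        p, q, n = 5, 4, 60
        stats = random_stats(p, q, n, rng)
        tol = 1e-10
        m = fit_from_stats(stats, 0.2, 0.15, FitOptions(tol=tol, max_iter=50000))
        assert m.fit_info["converged"]
        assert kkt_violation(m, stats) < 1e-5

    def test_objective_trace_monotone_and_lambda_pd(self, rng):
        p, q, n = 6, 4, 40
        stats = random_stats(p, q, n, rng)
        m = fit_from_stats(stats, 0.05, 0.05, FitOptions(tol=1e-8))
        trace = m.fit_info["objective_trace"]
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        np.linalg.cholesky(m.Lambda)  # PD or raises

    def test_gene_permutation_equivariance(self, rng):
        """Permuting gene order permutes the solution identically."""
        p, q, n = 5, 3, 80
        X = rng.standard_normal((n, q))
        X = (X - X.mean(0)) / X.std(0)
        Y = rng.standard_normal((n, p))
        Y -= Y.mean(0)
        opts = FitOptions(tol=1e-11, max_iter=50000)
        m1 = fit_from_stats(SufficientStats.from_arrays(X, Y), 0.1, 0.1, opts)
        perm = rng.permutation(p)
        m2 = fit_from_stats(SufficientStats.from_arrays(X, Y[:, perm]), 0.1, 0.1, opts)
        np.testing.assert_allclose(m2.Lambda, m1.Lambda[np.ix_(perm, perm)], atol=1e-8)
        np.testing.assert_allclose(m2.Theta, m1.Theta[:, perm], atol=1e-8)

    def test_large_lambda_perturb_zeroes_theta(self, rng):
        stats = random_stats(4, 3, 50, rng)
        m = fit_from_stats(stats, 0.05, 1e3, FitOptions(tol=1e-9))
        assert np.all(m.Theta == 0.0)

    def test_large_lambda_net_zeroes_offdiagonal(self, rng):
        stats = random_stats(4, 3, 50, rng)
        m = fit_from_stats(stats, 1e3, 0.05, FitOptions(tol=1e-9))
        off = m.Lambda[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    def test_nan_in_data_rejected(self):
        from scggm.model import GeneExpressionMatrix, GenotypeMatrix

        with pytest.raises(ValueError, match="NaN|finite"):
            GeneExpressionMatrix(np.array([[np.nan, 1.0]]), ["g1", "g2"], ["s1"])

    def test_nonconvergence_flagged_not_raised(self, rng):
        stats = random_stats(4, 3, 50, rng)
        m = fit_from_stats(stats, 0.01, 0.01, FitOptions(tol=0.0, max_iter=3))
        assert m.fit_info["converged"] is False


class TestFitPath:
    def test_single_point_equals_direct_fit(self, rng):
        X, Y, _ = simulate_cggm_dataset(p=6, q=8, n=60, seed=3)
        opts = FitOptions(tol=1e-9)
        path = fit_path(X, Y, [(0.1, 0.1)], opts)
        direct = fit_scggm(X, Y, 0.1, 0.1, opts)
        np.testing.assert_allclose(path[0].Lambda, direct.Lambda, atol=1e-6)
        np.testing.assert_allclose(path[0].Theta, direct.Theta, atol=1e-6)

    def test_duplicate_grid_points_identical(self, rng):
        X, Y, _ = simulate_cggm_dataset(p=5, q=6, n=50, seed=4)
        path = fit_path(X, Y, [(0.2, 0.2), (0.2, 0.2)], FitOptions(tol=1e-9))
        np.testing.assert_array_equal(path[0].Lambda, path[1].Lambda)
        np.testing.assert_array_equal(path[0].Theta, path[1].Theta)

    def test_warm_start_matches_cold_start(self, rng):
        X, Y, _ = simulate_cggm_dataset(p=5, q=6, n=50, seed=5)
        opts = FitOptions(tol=1e-10, max_iter=20000)
        grid = [(0.3, 0.3), (0.05, 0.05)]
        path = fit_path(X, Y, grid, opts)
        for (ln, lp), m in zip(grid, path):
            cold = fit_scggm(X, Y, ln, lp, opts)
            stats = SufficientStats.from_data(X.standardize(), Y.center())
            assert objective(m, stats, ln, lp) == pytest.approx(
                objective(cold, stats, ln, lp), abs=1e-6)

    def test_empty_grid_rejected(self, rng):
        X, Y, _ = simulate_cggm_dataset(p=4, q=4, n=30, seed=6)
        with pytest.raises(ValueError):
            fit_path(X, Y, [])


class TestCrossValidate:
    def test_single_point_grid_is_best(self):
        X, Y, _ = simulate_cggm_dataset(p=5, q=6, n=60, seed=7)
        res = cross_validate(X, Y, [(0.1, 0.1)], k=3, seed=0)
        assert res.best == (0.1, 0.1)

    def test_tie_break_prefers_sparser(self):
        X, Y, _ = simulate_cggm_dataset(p=5, q=6, n=60, seed=8)
        res = cross_validate(X, Y, [(0.1, 0.1), (0.1, 0.1)], k=3, seed=0)
        assert res.best == (0.1, 0.1)
        assert res.cv_errors[0]["mean"] == pytest.approx(res.cv_errors[1]["mean"])

    def test_matches_brute_force_fold_loop(self):
        """CV errors and selection agree with an independent fold-by-fold loop."""
        X, Y, _ = simulate_cggm_dataset(p=5, q=6, n=45, seed=9)
        grid = [(0.5, 0.5), (0.1, 0.1), (0.05, 0.3)]
        k, seed = 3, 123
        opts = FitOptions(tol=1e-9)
        res = cross_validate(X, Y, grid, k=k, opts=opts, seed=seed)

        n = Y.n_samples
        rng2 = np.random.default_rng(seed)
        perm = rng2.permutation(n)
        bounds = np.linspace(0, n, k + 1).astype(int)
        means = []
        for ln, lp in grid:
            errs = []
            for f in range(k):
                test_idx = perm[bounds[f]:bounds[f + 1]]
                train_idx = np.setdiff1d(perm, test_idx)
                Xtr_raw, Xte_raw = X.values[train_idx], X.values[test_idx]
                Ytr_raw, Yte_raw = Y.values[train_idx], Y.values[test_idx]
                xm, xs = Xtr_raw.mean(0), Xtr_raw.std(0)
                ym = Ytr_raw.mean(0)
                stats = SufficientStats.from_arrays((Xtr_raw - xm) / xs, Ytr_raw - ym)
                m = fit_from_stats(stats, ln, lp, opts)
                B, _ = indirect_effects(m)
                errs.append(prediction_error(B, (Xte_raw - xm) / xs, Yte_raw - ym))
            means.append(np.mean(errs))
        # warm-started path fits vs cold re-fits: agreement at solver accuracy
        for got, expect in zip(res.cv_errors, means):
            assert got["mean"] == pytest.approx(expect, rel=1e-4)
        assert res.best == grid[int(np.argmin(means))]

    def test_more_folds_than_samples_rejected(self):
        X, Y, _ = simulate_cggm_dataset(p=3, q=3, n=5, seed=10)
        with pytest.raises(ValueError):
            cross_validate(X, Y, [(0.1, 0.1)], k=10)


class TestFitOptionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_iter": 0},
            {"tol": -1e-3},
            {"backtracking_factor": 1.5},
            {"initial_step": 0.0},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitOptions(**kwargs)
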