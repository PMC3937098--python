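"""Generators: Laplacian networks, perturbations, genotypes, expressions."""

import numpy as np
import pytest

from scggm.model import SufficientStats
from scggm.simulate import (
    GroundTruth,
    NetworkSpec,
    make_direct_perturbations,
    make_module_network,
    make_scalefree_network,
    sample_expressions,
    sample_regression_design,
    simulate_cggm_dataset,
    simulate_genotypes,
)


class TestModuleNetwork:
    def test_two_gene_single_edge_closed_form(self):
        spec = NetworkSpec(p=2, n_modules=1, p_within=1.0, p_between=0.0,
                           weight_lo=0.5, weight_hi=0.5 + 1e-12,
                           diag_jitter=0.1, seed=0)
        Lam, modules = make_module_network(spec)
        w, d = 0.5, 0.1
        np.testing.assert_allclose(Lam, [[w + d, -w], [-w, w + d]], atol=1e-9)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(Lam)),
                                   [d, 2 * w + d], atol=1e-9)

    def test_no_edges_gives_jitter_diagonal(self):
        spec = NetworkSpec(p=6, p_within=0.0, p_between=0.0, diag_jitter=0.2, seed=1)
        Lam, _ = make_module_network(spec)
        np.testing.assert_allclose(Lam, 0.2 * np.eye(6), atol=1e-12)

    def test_laplacian_row_sums_and_pd(self):
        spec = NetworkSpec(p=30, n_modules=3, seed=42)
        Lam, modules = make_module_network(spec)
        # Laplacian row-sum identity: Λ·1 = jitter·1
        np.testing.assert_allclose(Lam @ np.ones(30), spec.diag_jitter, atol=1e-10)
        np.linalg.cholesky(Lam)
        assert sorted(g for mod in modules for g in mod) == list(range(30))

    def test_off_diagonal_weights_in_range(self):
        spec = NetworkSpec(p=20, p_within=0.5, p_between=0.1, seed=3)
        Lam, _ = make_module_network(spec)
        off = -Lam[~np.eye(20, dtype=bool)]
        nz = off[off != 0]
        assert np.all((nz >= spec.weight_lo) & (nz <= spec.weight_hi))

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(p=10, p_within=0.1, p_between=0.5)


class TestScaleFreeNetwork:
    def test_pd_and_symmetric_across_seeds(self):
        for seed in range(5):
            spec = NetworkSpec(p=40, topology="scalefree", seed=seed)
            Lam = make_scalefree_network(spec)
            np.testing.assert_allclose(Lam, Lam.T, atol=1e-12)
            np.linalg.cholesky(Lam)

    def test_degree_distribution_spans_a_decade_and_decreases(self):
        """Pooled over seeds, the log-log cumulative degree curve is heavy-tailed."""
        degrees = []
        for seed in range(10):
            spec = NetworkSpec(p=500, topology="scalefree", degree_exponent=2.5, seed=seed)
            Lam = make_scalefree_network(spec)
            adj = (np.abs(Lam) > 1e-12) & ~np.eye(500, dtype=bool)
            degrees.extend(adj.sum(1))
        degrees = np.asarray(degrees)
        pos = degrees[degrees > 0]
        assert pos.max() / max(pos.min(), 1) >= 10  # spans a decade
        uniq = np.unique(pos)
        frac = np.array([(pos >= d).mean() for d in uniq])
        assert np.all(np.diff(frac) < 0)

    def test_row_sum_identity(self):
        spec = NetworkSpec(p=50, topology="scalefree", seed=2)
        Lam = make_scalefree_network(spec)
        np.testing.assert_allclose(Lam @ np.ones(50), spec.diag_jitter, atol=1e-10)


class TestDirectPerturbations:
    def test_zero_probability_gives_zero_matrix(self):
        Th = make_direct_perturbations(5, 10, pattern="uniform", perturb_prob=0.0, seed=0)
        assert np.all(Th == 0)

    def test_per_module_pattern_restricted_columns(self):
        modules = [[0, 1, 2], [3, 4, 5], [6, 7, 8]]
        Th = make_direct_perturbations(9, 50, pattern="per_module_single_gene",
                                       perturb_prob=0.3, modules=modules, seed=1)
        nonzero_cols = np.flatnonzero(np.any(Th != 0, axis=0))
        assert len(nonzero_cols) <= 3
        for col in nonzero_cols:
            assert any(col in mod for mod in modules)

    def test_per_module_requires_modules(self):
        with pytest.raises(ValueError):
            make_direct_perturbations(5, 5, pattern="per_module_single_gene", seed=0)

    def test_uniform_nonzero_count_binomial(self):
        q, p, prob = 1000, 500, 0.01
        counts = [
            (make_direct_perturbations(p, q, pattern="uniform", perturb_prob=prob,
                                       seed=s) != 0).sum()
            for s in range(3)
        ]
        mean, sd = q * p * prob, np.sqrt(q * p * prob * (1 - prob))
        for c in counts:
            assert abs(c - mean) < 4 * sd

    def test_effect_magnitudes_in_range(self):
        Th = make_direct_perturbations(20, 50, pattern="uniform", perturb_prob=0.2,
                                       effect_lo=0.6, effect_hi=1.0, seed=5)
        nz = np.abs(Th[Th != 0])
        assert np.all((nz >= 0.6) & (nz <= 1.0))
        assert (Th > 0).any() and (Th < 0).any()  # random signs

    def test_hub_extra_adds_eqtls_for_hubs(self):
        Th = make_direct_perturbations(10, 30, pattern="hub_extra", perturb_prob=0.0,
                                       hub_genes=[2, 7], seed=6)
        assert np.any(Th[:, 2] != 0) and np.any(Th[:, 7] != 0)
        untouched = [j for j in range(10) if j not in (2, 7)]
        assert np.all(Th[:, untouched] == 0)


class TestGenotypes:
    def test_values_in_allele_counts(self):
        X = simulate_genotypes(50, 20, seed=0)
        assert np.isin(X.values, (0.0, 1.0, 2.0)).all()
        assert not X.standardized

    def test_no_ld_gives_near_zero_neighbor_correlation(self):
        X = simulate_genotypes(2000, 30, ld_decay=0.0, seed=1).standardize()
        r = [np.corrcoef(X.values[:, j], X.values[:, j + 1])[0, 1] for j in range(29)]
        assert np.max(np.abs(r)) < 0.1

    def test_ld_decay_induces_neighbor_correlation(self):
        X = simulate_genotypes(2000, 30, ld_decay=0.9, seed=2).standardize()
        r = [np.corrcoef(X.values[:, j], X.values[:, j + 1])[0, 1] for j in range(29)]
        assert np.median(r) > 0.4

    def test_allele_frequency_target(self):
        X = simulate_genotypes(2000, 40, maf_lo=0.5, maf_hi=0.5, seed=3)
        pooled = X.values.mean() / 2.0
        assert abs(pooled - 0.5) < 0.03

    def test_no_constant_columns(self):
        X = simulate_genotypes(30, 50, maf_lo=0.1, maf_hi=0.15, seed=4)
        assert np.all(X.values.std(axis=0) > 0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, maf_lo=0.0, maf_hi=0.5)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 5, ld_decay=1.0)


class TestExpressions:
    def _truth(self, rng, p=10, q=5):
        Lam = np.eye(p)
        Theta = np.zeros((q, p))
        return GroundTruth(Lambda_true=Lam, Theta_true=Theta,
                           B_true=-Theta @ np.linalg.inv(Lam))

    def test_identity_network_sample_covariance(self, rng):
        truth = self._truth(rng)
        X = simulate_genotypes(5000, 5, seed=0).standardize()
        Y = sample_expressions(truth, X, seed=1)
        C = np.cov(Y.values, rowvar=False)
        off = C[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1
        np.testing.assert_allclose(np.diag(C), 1.0, atol=0.15)

    def test_deterministic_given_seed(self, rng):
        truth = self._truth(rng)
        X = simulate_genotypes(50, 5, seed=0).standardize()
        Y1 = sample_expressions(truth, X, seed=7)
        Y2 = sample_expressions(truth, X, seed=7)
        np.testing.assert_array_equal(Y1.values, Y2.values)

    def test_residual_precision_recovers_truth(self):
        spec = NetworkSpec(p=10, seed=0)
        Lam, _ = make_module_network(spec)
        Theta = make_direct_perturbations(10, 8, pattern="uniform",
                                          perturb_prob=0.2, seed=1)
        truth = GroundTruth(Lambda_true=Lam, Theta_true=Theta,
                            B_true=-np.linalg.solve(Lam, Theta.T).T)
        X = simulate_genotypes(5000, 8, seed=2).standardize()
        Y = sample_expressions(truth, X, seed=3)
        resid = Y.values - X.values @ truth.B_true
        emp_prec = np.linalg.inv(np.cov(resid, rowvar=False))
        rel_err = np.linalg.norm(emp_prec - Lam) / np.linalg.norm(Lam)
        assert rel_err < 0.15


class TestRegressionDesign:
    def test_pleiotropic_support_shared_within_module(self):
        X, Y, truth = sample_regression_design(p=12, q=30, n=50, eqtl_prob=0.2, seed=0)
        for genes in truth.modules:
            sup = truth.B_true[:, genes] != 0
            # every SNP either hits all genes of the module or none
            assert np.all(sup.all(axis=1) == sup.any(axis=1))

    def test_zero_effects_give_pure_noise(self):
        X, Y, truth = sample_regression_design(p=6, q=10, n=40, eqtl_prob=0.0, seed=1)
        assert np.all(truth.B_true == 0)

    def test_least_squares_recovers_effects(self):
        X, Y, truth = sample_regression_design(p=6, q=8, n=20000, eqtl_prob=0.3,
                                               ld_decay=0.0, seed=2)
        Bhat, *_ = np.linalg.lstsq(X.standardize().values, Y.values, rcond=None)
        assert np.max(np.abs(Bhat - truth.B_true)) < 0.1

    def test_truth_internally_consistent(self):
        _, _, truth = sample_regression_design(p=8, q=10, n=30, seed=3)
        lhs = truth.B_true @ truth.Lambda_true
        assert np.max(np.abs(lhs + truth.Theta_true)) < 1e-10


class TestDatasetDeterminism:
    def test_identical_seeds_identical_outputs(self):
        d1 = simulate_cggm_dataset(p=8, q=10, n=30, seed=99)
        d2 = simulate_cggm_dataset(p=8, q=10, n=30, seed=99)
        np.testing.assert_array_equal(d1[0].values, d2[0].values)
        np.testing.assert_array_equal(d1[1].values, d2[1].values)
        np.testing.assert_array_equal(d1[2].Lambda_true, d2[2].Lambda_true)

    def test_b_true_consistency(self):
        *_, truth = simulate_cggm_dataset(p=8, q=10, n=30, seed=5)
        assert np.max(np.abs(truth.B_true @ truth.Lambda_true + truth.Theta_true)) < 1e-10
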