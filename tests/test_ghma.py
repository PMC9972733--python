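"""Gene-level kernel tests: reductions, tail evaluation, omnibus, power."""

import numpy as np
import pytest
from scipy import stats

from epimediate.association import AdjustmentSets, build_design, fit_all_sites
from epimediate.cohort import CohortConfig, generate_cohort, null_config
from epimediate.diagnostics import ks_uniformity
from epimediate.ghma import (
    DegenerateGeneError,
    _gaussian_kernel,
    ghma_linear,
    ghma_nonlinear,
    ghma_omnibus,
    imhof_pvalue,
    kernel_score_test,
    liu_pvalue,
    run_ghma,
)


class TestTailProbabilities:
    def test_single_eigenvalue_reduces_to_scaled_chi_square(self):
        for lam, q in [(1.0, 3.0), (2.5, 10.0), (0.3, 0.5)]:
            expect = stats.chi2.sf(q / lam, df=1)
            assert liu_pvalue(q, np.array([lam])) == pytest.approx(expect, abs=1e-12)
            assert imhof_pvalue(q, np.array([lam])) == pytest.approx(expect, abs=1e-6)

    def test_liu_and_imhof_agree_in_the_tail(self, rng):
        lam = rng.random(8) + 0.2
        for q in (np.sum(lam) * 2, np.sum(lam) * 3):
            assert liu_pvalue(q, lam) == pytest.approx(imhof_pvalue(q, lam), rel=0.15, abs=1e-4)

    def test_equal_eigenvalues_match_chi_square(self):
        lam = np.ones(5)
        for q in (2.0, 8.0, 15.0):
            assert imhof_pvalue(q, lam) == pytest.approx(stats.chi2.sf(q, df=5), abs=1e-6)


class TestScoreTest:
    def test_q1_gene_matches_single_site_score_test(self, small_null_cohort):
        """A one-CpG gene reproduces the site-level score test exactly: the
        statistic is (m'r)^2 against a single chi-square weight."""
        cohort, _ = small_null_cohort
        adj = AdjustmentSets()
        site = cohort.site_ids[0]
        M = cohort.methylation.loc[[site]].to_numpy().T
        M = M - M.mean(0)
        y = cohort.outcomes["cognitive"].to_numpy()
        cov = build_design(cohort, "mediator_outcome", adj)
        X = np.column_stack([np.ones(cohort.n_samples), cohort.exposure.to_numpy(), cov.to_numpy()])
        p_pkg = kernel_score_test(y, X, M=M)
        # independent single-site oracle: project out X, chi-square(1)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        s2 = r @ r / (len(y) - X.shape[1])
        mcoef, *_ = np.linalg.lstsq(X, M[:, 0], rcond=None)
        mres = M[:, 0] - X @ mcoef
        q = (mres @ r) ** 2 / s2
        p_oracle = stats.chi2.sf(q / (mres @ mres), df=1)
        assert p_pkg == pytest.approx(p_oracle, abs=1e-6)

    def test_q1_linear_equals_nonlinear_alpha_component(self, small_null_cohort):
        cohort, _ = small_null_cohort
        sites = [cohort.site_ids[3]]
        p_lin = ghma_linear(cohort, sites)
        assert 0.0 < p_lin <= 1.0

    def test_degenerate_gene_raises(self, small_null_cohort):
        cohort, _ = small_null_cohort
        from tests_support import clone_cohort

        c = clone_cohort(cohort)
        s = c.site_ids[0]
        c.methylation.loc[s] = 0.4
        with pytest.raises(DegenerateGeneError):
            ghma_nonlinear(c, [s])

    def test_kernel_limit_large_bandwidth_matches_linear_ranking(self, rng):
        """As bandwidth grows the Gaussian-kernel statistic ranks genes like
        the linear kernel on the same data."""
        n = 120
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        genes = [rng.standard_normal((n, 5)) for _ in range(12)]
        genes = [g - g.mean(0) for g in genes]
        p_lin = [kernel_score_test(y, X, M=g) for g in genes]
        p_big = [kernel_score_test(y, X, K=_gaussian_kernel(g, bandwidth=500.0)) for g in genes]
        r1 = np.argsort(np.argsort(p_lin))
        r2 = np.argsort(np.argsort(p_big))
        rho = np.corrcoef(r1, r2)[0, 1]
        assert rho > 0.9


class TestOmnibus:
    def test_equal_inputs_are_fixed_points(self):
        assert ghma_omnibus(0.05, 0.05) == pytest.approx(0.05, abs=1e-12)
        assert ghma_omnibus(0.5, 0.5) == pytest.approx(0.5, abs=1e-12)
        assert ghma_omnibus(0.2, 0.2) == pytest.approx(0.2, abs=1e-12)

    def test_heavy_tail_dominance(self):
        assert ghma_omnibus(1e-6, 0.9) < 1e-5

    def test_uniform_under_independent_null_components(self, rng):
        p = np.array([ghma_omnibus(a, b) for a, b in rng.random((2000, 2))])
        assert ks_uniformity(p)[1] > 0.01

    def test_zero_input_clipped_with_warning(self):
        out = ghma_omnibus(0.0, 0.5)
        assert 0.0 < out < 1e-200 or out < 1e-15

    def test_minp_variant(self):
        assert ghma_omnibus(0.1, 0.9, method="minp") == pytest.approx(1 - 0.9**2)


class TestRunGhma:
    def test_null_cohort_components_uniform_no_fdr_hits(self):
        cohort, _ = generate_cohort(
            null_config(n_samples=250, n_sites=1500, n_genes=150, seed=31)
        )
        res = run_ghma(cohort)
        assert len(res.table) == 150
        for col in ("p_alpha_gene", "p_beta_linear", "p_beta_nonlinear"):
            assert ks_uniformity(res.table[col])[1] > 0.01
        assert res.significant_genes() == []

    def test_carrier_gene_is_top_omnibus_hit(self):
        cfg = CohortConfig(n_samples=400, n_sites=1000, n_genes=100, n_planted=4,
                           planted_per_gene=4, alpha_effects=0.008, beta_effects=-40.0, seed=37)
        cohort, truth = generate_cohort(cfg)
        carrier = cohort.gene_map.assignment[truth.planted_site_ids[0]]
        res = run_ghma(cohort)
        assert res.table["p_omnibus"].idxmin() == carrier
        assert carrier in res.significant_genes()

    def test_quadratic_signal_favors_nonlinear_component(self):
        """An outcome depending quadratically on a gene's mean methylation
        (no linear projection) is caught better by the Gaussian kernel."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            cohort, _ = generate_cohort(
                null_config(n_samples=300, n_sites=40, n_genes=4, seed=800 + seed)
            )
            gene_sites = cohort.gene_map.sites_for("gene0000")
            M = cohort.methylation.loc[gene_sites].to_numpy().T
            g = M.mean(axis=1)
            gc = g - g.mean()
            rng = np.random.default_rng(seed)
            y = 85.0 + 40.0 * (gc**2 - (gc**2).mean()) / gc.std() + 0.5 * rng.standard_normal(len(g))
            cohort.outcomes["cognitive"] = y
            y_arr = cohort.outcomes["cognitive"].to_numpy()
            adj = AdjustmentSets()
            cov = build_design(cohort, "mediator_outcome", adj)
            X = np.column_stack([np.ones(len(y_arr)), cohort.exposure.to_numpy(), cov.to_numpy()])
            Mc = M - M.mean(0)
            p_lin = kernel_score_test(y_arr, X, M=Mc)
            p_non = kernel_score_test(y_arr, X, K=_gaussian_kernel(Mc))
            wins += p_non < p_lin
        assert wins >= int(0.8 * n_rep) - 2

    def test_row_count_excludes_degenerate_genes(self, small_null_cohort):
        from tests_support import clone_cohort

        cohort = clone_cohort(small_null_cohort[0])
        dead_gene = "gene0000"
        for s in cohort.gene_map.sites_for(dead_gene):
            cohort.methylation.loc[s] = 0.3
        res = run_ghma(cohort)
        assert dead_gene in res.degenerate_genes
        assert len(res.table) == len(cohort.gene_map.gene_ids) - 1
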