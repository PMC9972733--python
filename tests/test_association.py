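"""Association engine: OLS correctness, PCs, sweeps, invariances, null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimediate.association import (
    AdjustmentSets,
    DegenerateSiteError,
    compute_pcs,
    fit_all_sites,
    fit_path,
)
from epimediate.cohort import generate_cohort, null_config
from epimediate.diagnostics import ks_uniformity


def ols_oracle(X, y):
    """Independent normal-equations + t-CDF oracle (no shared code path)."""
    XtX = X.T @ X
    b = np.linalg.solve(XtX, X.T @ y)
    r = y - X @ b
    df = len(y) - X.shape[1]
    s2 = float(r @ r) / df
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    t = b / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return b, se, p, df


class TestComputePcs:
    def test_simplex_rank_deficiency(self, rng):
        comp = rng.dirichlet(np.ones(7), size=100)
        scores = compute_pcs(comp, 6)
        variances = scores.var(axis=0)
        assert (variances > 1e-12).sum() <= 6

    def test_leading_eigenvector_of_known_covariance(self, rng):
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        X = rng.multivariate_normal([0, 0], cov, size=5000)
        scores = compute_pcs(X, 2)
        # recover the loading direction from a regression of scores on data
        v = np.linalg.lstsq(X - X.mean(0), scores[:, 0], rcond=None)[0]
        v /= np.linalg.norm(v)
        target = np.array([1.0, 1.0]) / np.sqrt(2.0)
        angle = np.degrees(np.arccos(np.clip(abs(v @ target), -1, 1)))
        assert angle < 2.0

    def test_shape_contract_and_guards(self, rng):
        X = rng.standard_normal((30, 7))
        assert compute_pcs(X, 3).shape == (30, 3)
        with pytest.raises(ValueError):
            compute_pcs(np.ones((10, 4)), 2)
        with pytest.raises(ValueError):
            compute_pcs(X, 10)


class TestFitPath:
    def test_noiseless_mediator_recovers_slope_exactly(self, small_null_cohort):
        cohort, _ = small_null_cohort
        cohort = _clone(cohort)
        site = cohort.site_ids[0]
        cohort.methylation.loc[site] = 0.01 * cohort.exposure.to_numpy() / 50.0 + 0.3
        adj = AdjustmentSets(em_covariates=(), n_celltype_pcs=0, n_ancestry_pcs=0)
        rec = fit_path(cohort, "exposure_mediator", site, adjustment=adj)
        assert rec["estimate"] == pytest.approx(0.01 / 50.0, abs=1e-10)
        assert rec["p"] < 1e-200

    def test_hand_oracle_small_design(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        m = np.array([2.0, 4.1, 4.9, 8.2, 9.1, 12.8])
        X = np.column_stack([np.ones(6), x])
        b, se, p, df = ols_oracle(X, m)
        # textbook closed form for simple regression
        slope = np.sum((x - x.mean()) * (m - m.mean())) / np.sum((x - x.mean()) ** 2)
        assert b[1] == pytest.approx(slope, abs=1e-12)
        resid = m - X @ b
        s2 = resid @ resid / 4
        se_slope = np.sqrt(s2 / np.sum((x - x.mean()) ** 2))
        assert se[1] == pytest.approx(se_slope, abs=1e-12)
        assert p[1] == pytest.approx(2 * stats.t.sf(abs(slope / se_slope), 4), abs=1e-15)

    def test_degenerate_site_raises(self, small_null_cohort):
        cohort, _ = small_null_cohort
        cohort = _clone(cohort)
        site = cohort.site_ids[1]
        cohort.methylation.loc[site] = 0.5
        with pytest.raises(DegenerateSiteError):
            fit_path(cohort, "mediator_outcome", site)

    def test_sweep_agrees_with_statsmodels(self, small_null_cohort):
        """Epigenome-wide sweep equals a per-site statsmodels OLS fit."""
        sm = pytest.importorskip("statsmodels.api")
        cohort, _ = small_null_cohort
        adj = AdjustmentSets()
        alpha, beta = fit_all_sites(cohort, adjustment=adj)
        from epimediate.association import build_design

        e = cohort.exposure.to_numpy()
        y = cohort.outcomes["cognitive"].to_numpy()
        mo = build_design(cohort, "mediator_outcome", adj).to_numpy()
        em = build_design(cohort, "exposure_mediator", adj).to_numpy()
        for site in cohort.site_ids[:8]:
            mvals = cohort.methylation.loc[site].to_numpy()
            X = sm.add_constant(np.column_stack([e, em]))
            fit = sm.OLS(mvals, X).fit()
            assert alpha.table.loc[site, "estimate"] == pytest.approx(fit.params[1], abs=1e-10)
            assert alpha.table.loc[site, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)
            Xb = sm.add_constant(np.column_stack([mvals, e, mo]))
            fitb = sm.OLS(y, Xb).fit()
            assert beta.table.loc[site, "estimate"] == pytest.approx(fitb.params[1], abs=1e-8)
            assert beta.table.loc[site, "gamma_prime"] == pytest.approx(fitb.params[2], abs=1e-8)
            assert beta.table.loc[site, "gamma_prime_p"] == pytest.approx(fitb.pvalues[2], abs=1e-8)

    def test_exposure_affine_invariance(self, small_null_cohort):
        """Scaling the exposure by c scales alpha-hat and gamma-hat' by 1/c."""
        cohort, _ = small_null_cohort
        a1, b1 = fit_all_sites(cohort)
        scaled = _clone(cohort)
        scaled.exposure = cohort.exposure * 10.0
        a2, b2 = fit_all_sites(scaled)
        np.testing.assert_allclose(a2.table["estimate"], a1.table["estimate"] / 10.0, atol=1e-8)
        np.testing.assert_allclose(b2.table["gamma_prime"], b1.table["gamma_prime"] / 10.0, atol=1e-8)
        np.testing.assert_allclose(a2.table["p"], a1.table["p"], atol=1e-10)
        # adding a constant changes nothing but the intercept
        shifted = _clone(cohort)
        shifted.exposure = cohort.exposure + 500.0
        a3, _ = fit_all_sites(shifted)
        np.testing.assert_allclose(a3.table["estimate"], a1.table["estimate"], atol=1e-8)

    def test_degenerate_sites_reported_in_skip_list(self, small_null_cohort):
        cohort, _ = small_null_cohort
        cohort = _clone(cohort)
        bad = cohort.site_ids[5]
        cohort.methylation.loc[bad] = 0.25
        alpha, beta = fit_all_sites(cohort)
        assert alpha.skipped == [bad] and beta.skipped == [bad]
        assert len(alpha.table) == len(cohort.site_ids) - 1

    def test_null_p_values_ks_uniform(self):
        cohort, _ = generate_cohort(
            null_config(n_samples=300, n_sites=2000, n_genes=200, block_rho=0.0, seed=29)
        )
        alpha, beta = fit_all_sites(cohort, scale="mvalue")
        assert ks_uniformity(alpha.table["p"])[1] > 0.01
        assert ks_uniformity(beta.table["p"])[1] > 0.01

    def test_birth_weight_never_adjustable(self):
        with pytest.raises(ValueError):
            AdjustmentSets(mo_covariates=("ses", "birth_weight"))

    def test_hiv_sensitivity_adds_one_column(self, small_null_cohort):
        from epimediate.association import build_design

        cohort, _ = small_null_cohort
        base = build_design(cohort, "mediator_outcome", AdjustmentSets())
        hiv = build_design(cohort, "mediator_outcome", AdjustmentSets(include_hiv=True))
        assert hiv.shape[1] == base.shape[1] + 1
        assert "maternal_hiv" in hiv.columns


def _clone(cohort):
    from epimediate.cohort import Cohort

    return Cohort(
        methylation=cohort.methylation.copy(),
        site_table=cohort.site_table.copy(),
        exposure=cohort.exposure.copy(),
        outcomes=cohort.outcomes.copy(),
        covariates=cohort.covariates.copy(),
        gene_map=cohort.gene_map,
    )
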