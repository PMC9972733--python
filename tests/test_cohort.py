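"""Generator contracts: determinism, calibration, transforms, gene annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epimediate.cohort import (
    CohortConfig,
    assign_closest_gene,
    beta_to_mvalue,
    generate_cohort,
    mvalue_to_beta,
    null_config,
)


class TestGenerateCohort:
    def test_fixed_seed_determinism(self):
        cfg = CohortConfig(n_samples=60, n_sites=100, n_genes=10, n_planted=5, seed=7)
        c1, t1 = generate_cohort(cfg)
        c2, t2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.methylation, c2.methylation)
        pd.testing.assert_frame_equal(c1.outcomes, c2.outcomes)
        pd.testing.assert_series_equal(c1.exposure, c2.exposure)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_marginal_calibration_at_large_n(self):
        cfg = null_config(n_samples=10_000, n_sites=20, n_genes=5, seed=3)
        cohort, _ = generate_cohort(cfg)
        e = cohort.exposure.to_numpy()
        se_mean = cfg.exposure_sd / np.sqrt(cfg.n_samples)
        assert abs(e.mean() - 64.6) < 3 * se_mean
        assert abs(e.std() / 96.8 - 1.0) < 0.15  # heavy-tailed SD converges slowly
        y = cohort.outcomes["cognitive"].to_numpy()
        assert abs(y.mean() - 85.14) < 3 * 8.65 / np.sqrt(cfg.n_samples)
        assert abs(y.std() - 8.65) < 0.3

    def test_methylation_strictly_inside_unit_interval(self, small_null_cohort):
        vals = small_null_cohort[0].methylation.to_numpy()
        assert vals.min() > 0.0 and vals.max() < 1.0

    def test_celltype_proportions_sum_to_one(self, small_null_cohort):
        cohort = small_null_cohort[0]
        ct = cohort.covariates[cohort.celltype_columns].to_numpy()
        np.testing.assert_allclose(ct.sum(axis=1), 1.0, atol=1e-9)

    def test_truth_set_nie_identity_and_membership(self, planted_cohort):
        _, truth = planted_cohort
        tab = truth.table
        np.testing.assert_array_equal(tab["nie"].to_numpy(), (tab["alpha"] * tab["beta"]).to_numpy())
        assert len(tab) == 3

    def test_planted_alpha_recovered_at_large_n(self):
        """Regressing a planted site's M-values on exposure with the correct
        adjustment recovers the latent slope within 3 standard errors."""
        cfg = CohortConfig(n_samples=4000, n_sites=50, n_genes=10, n_planted=2,
                           alpha_effects=0.004, beta_effects=-15.0, seed=9)
        cohort, truth = generate_cohort(cfg)
        site = truth.planted_site_ids[0]
        m = beta_to_mvalue(cohort.methylation.loc[site].to_numpy())
        e = cohort.exposure.to_numpy()
        X = np.column_stack([np.ones(len(e)), e, cohort.covariates["ses"].to_numpy()])
        coef, _, _, _ = np.linalg.lstsq(X, m, rcond=None)
        resid = m - X @ coef
        se = np.sqrt(resid @ resid / (len(e) - 3) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(coef[1] - 0.004) < 3 * se

    def test_confounding_is_real(self):
        """Unadjusted and SES-adjusted exposure→outcome slopes differ by more
        than the slope SE, so adjustment-set logic is exercised."""
        cfg = null_config(n_samples=20_000, n_sites=10, n_genes=2, direct_effect=0.0, seed=13)
        cohort, _ = generate_cohort(cfg)
        e = cohort.exposure.to_numpy()
        y = cohort.outcomes["cognitive"].to_numpy()
        X1 = np.column_stack([np.ones(len(e)), e])
        b1 = np.linalg.lstsq(X1, y, rcond=None)[0][1]
        X2 = np.column_stack([X1, cohort.covariates["ses"].to_numpy()])
        b2, _, _, _ = np.linalg.lstsq(X2, y, rcond=None)
        resid = y - X2 @ b2
        se = np.sqrt(resid @ resid / (len(e) - 3) * np.linalg.inv(X2.T @ X2)[1, 1])
        assert abs(b1 - b2[1]) > se

    def test_null_exposure_slope_ci_covers_zero(self):
        """With nothing planted and no direct effect, the adjusted
        exposure→outcome slope CI covers 0 in at least 90/100 seeds."""
        hits = 0
        for seed in range(100):
            cfg = null_config(n_samples=150, n_sites=5, n_genes=1, seed=3000 + seed)
            cohort, _ = generate_cohort(cfg)
            e = cohort.exposure.to_numpy()
            y = cohort.outcomes["cognitive"].to_numpy()
            X = np.column_stack([np.ones(len(e)), e,
                                 cohort.covariates[["ses", "sex_female"]].to_numpy(),
                                 (cohort.covariates["smoking"] == 2).to_numpy(float)])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            se = np.sqrt(resid @ resid / (len(e) - X.shape[1]) * np.linalg.inv(X.T @ X)[1, 1])
            hits += abs(coef[1]) <= 1.96 * se
        assert hits >= 90

    @pytest.mark.parametrize("bad", [
        dict(n_samples=0), dict(block_rho=1.0), dict(exposure_sd=-1.0),
        dict(n_planted=10, n_sites=5), dict(n_planted=2, beta_effects=0.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortConfig(**bad)


class TestTransforms:
    @given(st.lists(st.floats(min_value=1e-6, max_value=1 - 1e-6), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_logit_logistic_round_trip(self, betas):
        b = np.asarray(betas)
        np.testing.assert_allclose(mvalue_to_beta(beta_to_mvalue(b)), b, atol=1e-9)


class TestClosestGene:
    @staticmethod
    def _tables(sites, genes):
        site_table = pd.DataFrame(
            {"chrom": [c for c, _ in sites], "pos": [p for _, p in sites]},
            index=pd.Index([f"s{i}" for i in range(len(sites))], name="site"),
        )
        gene_table = pd.DataFrame(
            {"chrom": [c for c, _, _ in genes], "start": [s for _, s, _ in genes],
             "end": [e for _, _, e in genes]},
            index=pd.Index([f"g{i}" for i in range(len(genes))], name="gene"),
        )
        return site_table, gene_table

    def test_containment_wins(self):
        st_, gt = self._tables([("chr1", 150)], [("chr1", 100, 200), ("chr1", 300, 400)])
        gm = assign_closest_gene(st_, gt)
        assert gm.assignment["s0"] == "g0"

    def test_equidistant_tie_goes_to_lower_start(self):
        st_, gt = self._tables([("chr1", 250)], [("chr1", 100, 200), ("chr1", 300, 400)])
        gm = assign_closest_gene(st_, gt)
        assert gm.assignment["s0"] == "g0"

    def test_missing_chromosome_flagged_not_dropped(self):
        st_, gt = self._tables([("chr2", 10)], [("chr1", 0, 100)])
        gm = assign_closest_gene(st_, gt)
        assert "s0" in gm.assignment.index and pd.isna(gm.assignment["s0"])

    def test_degenerate_interval_rejected(self):
        st_, gt = self._tables([("chr1", 10)], [("chr1", 100, 100)])
        with pytest.raises(ValueError):
            assign_closest_gene(st_, gt)

    @given(
        pos=st.lists(st.integers(0, 20_000), min_size=1, max_size=20),
        genes=st.lists(
            st.tuples(st.integers(0, 19_000), st.integers(1, 900)), min_size=1, max_size=10
        ),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_exhaustive_distance_scan(self, pos, genes):
        sites = [("chr1", p) for p in pos]
        gtuples = [("chr1", s, s + w) for s, w in genes]
        st_, gt = self._tables(sites, gtuples)
        gm = assign_closest_gene(st_, gt)

        def dist(p, s, e):
            return max(s - p, p - e, 0)

        for i, (_, p) in enumerate(sites):
            best = min(
                ((dist(p, s, e), s, g) for g, (_, s, e) in zip(gt.index, gtuples)),
                key=lambda t: (t[0], t[1], t[2]),
            )
            assert gm.assignment[f"s{i}"] == best[2]
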