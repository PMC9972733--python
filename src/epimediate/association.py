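"""Covariate-adjusted per-site linear models for the two mediation paths.

The exposure→mediator ("alpha path") model regresses each site's methylation
on exposure plus the exposure–mediator adjustment set; the mediator→outcome
("beta path") model regresses the developmental score on methylation plus
exposure plus the mediator–outcome adjustment set, so the exposure coefficient
of the beta-path model is the per-site direct effect gamma'.

Default adjustment sets follow the minimal sufficient sets of the study DAGs:
exposure–mediator models adjust for SES, maternal smoking, genetic-ancestry
scores and cell-type principal components; mediator–outcome models adjust for
maternal alcohol use, maternal age, SES, child sex, maternal smoking, ancestry
and cell-type PCs (maternal HIV optionally, as a sensitivity variant).  Birth
weight is deliberately never adjusted for: it is a potential downstream
mediator, not a confounder.

All sweeps are exact ordinary least squares; the epigenome-wide beta-path
sweep uses a rank-one design augmentation of a shared covariate block, which
equals the site-by-site fit to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, beta_to_mvalue

__all__ = [
    "AdjustmentSets",
    "PathEstimates",
    "DegenerateSiteError",
    "compute_pcs",
    "fit_path",
    "fit_all_sites",
]


class DegenerateSiteError(ValueError):
    """Raised for a site whose methylation has no variance."""


@dataclass
class AdjustmentSets:
    """Covariate configuration for the two path models.

    ``celltype_paths`` controls which models receive the cell-type PCs
    ("both", "em", "mo"); the default applies them to both paths.
    """

    em_covariates: tuple[str, ...] = ("ses", "smoking")
    mo_covariates: tuple[str, ...] = ("alcohol", "maternal_age", "ses", "sex_female", "smoking")
    n_celltype_pcs: int = 3
    n_ancestry_pcs: int = 5
    include_hiv: bool = False
    celltype_paths: str = "both"

    def __post_init__(self) -> None:
        banned = {"birth_weight", "birthweight"}
        if banned & set(self.em_covariates) or banned & set(self.mo_covariates):
            raise ValueError("birth weight is a downstream mediator and must not be adjusted for")
        if self.celltype_paths not in ("both", "em", "mo"):
            raise ValueError("celltype_paths must be 'both', 'em' or 'mo'")


def compute_pcs(matrix: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component scores of a samples × features matrix.

    Columns are centered; scores are projections onto the leading
    eigenvectors of the covariance, with variances in non-increasing order.
    The sign of each component is fixed so that its largest-magnitude loading
    is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (samples × features)")
    if np.any(~np.isfinite(X)):
        raise ValueError("matrix contains missing or non-finite values")
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(n_samples - 1, n_features)")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise ValueError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * s
    return (scores * flip)[:, :n_components]


@dataclass
class PathEstimates:
    """Per-site OLS estimates for one causal path.

    ``table`` is indexed by site with columns estimate, se, t, p, df and — for
    the beta path — gamma_prime, gamma_prime_se, gamma_prime_p.
    """

    path: str
    table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    @property
    def sites(self) -> pd.Index:
        return self.table.index

    def p_values(self) -> pd.Series:
        return self.table["p"]


def _expand_design(covariates: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame:
    """Expand named covariates to numeric columns (smoking → two indicators).

    Reference levels: non-smoker, no alcohol, male, HIV-negative.
    """
    cols: dict[str, np.ndarray] = {}
    for name in names:
        if name == "smoking":
            smk = covariates["smoking"].to_numpy()
            cols["smoking_passive"] = (smk == 1).astype(float)
            cols["smoking_active"] = (smk == 2).astype(float)
        else:
            if name not in covariates.columns:
                raise KeyError(f"covariate {name!r} not present in cohort")
            cols[name] = covariates[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=covariates.index)


def build_design(cohort: Cohort, path: str, adjustment: AdjustmentSets) -> pd.DataFrame:
    """Covariate block (no intercept, no exposure/mediator) for one path."""
    if path not in ("exposure_mediator", "mediator_outcome"):
        raise ValueError(f"unknown path {path!r}")
    names = adjustment.em_covariates if path == "exposure_mediator" else adjustment.mo_covariates
    if path == "mediator_outcome" and adjustment.include_hiv:
        names = names + ("maternal_hiv",)
    design = _expand_design(cohort.covariates, names)
    anc = cohort.ancestry_columns[: adjustment.n_ancestry_pcs]
    for c in anc:
        design[c] = cohort.covariates[c].to_numpy(dtype=float)
    use_ct = adjustment.celltype_paths == "both" or (
        (path == "exposure_mediator") == (adjustment.celltype_paths == "em")
    )
    if use_ct and adjustment.n_celltype_pcs > 0:
        ct = cohort.covariates[cohort.celltype_columns].to_numpy(dtype=float)
        pcs = compute_pcs(ct, adjustment.n_celltype_pcs)
        for i in range(adjustment.n_celltype_pcs):
            design[f"celltype_pc{i + 1}"] = pcs[:, i]
    return design


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated via the smallest right-singular vectors
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        bad = Vt[rank:]
        implicated = sorted({names[j] for row in bad for j in np.argsort(-np.abs(row))[:3]})
        raise ValueError(f"rank-deficient design; collinear columns involve: {implicated}")


def _mediator_values(cohort: Cohort, sites, scale: str) -> np.ndarray:
    M = cohort.methylation.loc[sites].to_numpy(dtype=float).T  # samples × sites
    if scale == "mvalue":
        M = beta_to_mvalue(M)
    elif scale != "beta":
        raise ValueError("scale must be 'beta' or 'mvalue'")
    return M


def _ols_alpha_sweep(X: np.ndarray, Y: np.ndarray, coef_idx: int) -> tuple[np.ndarray, ...]:
    """OLS of many responses on one design; returns stats for one coefficient."""
    n, k = X.shape
    G = np.linalg.inv(X.T @ X)
    B = G @ (X.T @ Y)
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * G[coef_idx, coef_idx])
    est = B[coef_idx]
    t = est / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return est, se, t, p, df


def _ols_beta_sweep(
    X0: np.ndarray, y: np.ndarray, Z: np.ndarray, exposure_idx: int
) -> dict[str, np.ndarray]:
    """Per-site OLS of y on [X0, z_j] via rank-one augmentation of X0.

    X0 is the shared block (intercept + exposure + covariates), Z the
    samples × sites mediator matrix.  Returns the mediator coefficient stats
    and the exposure (direct-effect) coefficient stats for every site.
    """
    n, k = X0.shape
    G = np.linalg.inv(X0.T @ X0)
    Xty = X0.T @ y
    b0 = G @ Xty
    y_res = y - X0 @ b0
    A = G @ (X0.T @ Z)  # k × m, regression of each z on X0
    Z_res = Z - X0 @ A
    znorm2 = (Z_res**2).sum(axis=0)
    zy = Z_res.T @ y_res
    beta = zy / znorm2
    rss = (y_res**2).sum() - beta**2 * znorm2
    df = n - k - 1
    sigma2 = rss / df
    se = np.sqrt(sigma2 / znorm2)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # exposure coefficient in the augmented model
    gamma = b0[exposure_idx] - beta * A[exposure_idx]
    var_gamma = sigma2 * (G[exposure_idx, exposure_idx] + A[exposure_idx] ** 2 / znorm2)
    gamma_se = np.sqrt(var_gamma)
    gamma_t = gamma / gamma_se
    gamma_p = 2.0 * stats.t.sf(np.abs(gamma_t), df)
    return {
        "estimate": beta, "se": se, "t": t, "p": p, "df": np.full(Z.shape[1], df),
        "gamma_prime": gamma, "gamma_prime_se": gamma_se, "gamma_prime_p": gamma_p,
    }


def fit_all_sites(
    cohort: Cohort,
    outcome_domain: str = "cognitive",
    adjustment: AdjustmentSets | None = None,
    scale: str = "beta",
    sites=None,
) -> tuple[PathEstimates, PathEstimates]:
    """Fit both path models for every site (or a subset).

    Degenerate (zero-variance) sites are reported in each result's ``skipped``
    list rather than silently dropped.  Samples missing the requested outcome
    are excluded from both models (complete-case rule), so the two paths see
    the same analysis set.
    """
    adjustment = adjustment or AdjustmentSets()
    if cohort.n_samples == 0:
        raise ValueError("empty cohort")
    if outcome_domain not in cohort.outcomes.columns:
        raise KeyError(f"outcome domain {outcome_domain!r} not in cohort")
    site_list = list(sites) if sites is not None else cohort.site_ids

    y_all = cohort.outcomes[outcome_domain]
    keep = y_all.notna().to_numpy()
    sub = cohort if keep.all() else _subset_samples(cohort, y_all.index[keep])
    y = sub.outcomes[outcome_domain].to_numpy(dtype=float)
    e = sub.exposure.to_numpy(dtype=float)
    n = len(y)

    M = _mediator_values(sub, site_list, scale)
    variances = M.var(axis=0)
    good = variances > 0.0
    skipped = [s for s, g in zip(site_list, good) if not g]
    kept_sites = [s for s, g in zip(site_list, good) if g]
    M = M[:, good]

    em_cov = build_design(sub, "exposure_mediator", adjustment)
    X_em = np.column_stack([np.ones(n), e, em_cov.to_numpy(dtype=float)])
    _check_full_rank(X_em, ["intercept", "exposure", *em_cov.columns])
    est, se, t, p, df = _ols_alpha_sweep(X_em, M, coef_idx=1)
    alpha = PathEstimates(
        path="exposure_mediator",
        table=pd.DataFrame(
            {"estimate": est, "se": se, "t": t, "p": p, "df": df},
            index=pd.Index(kept_sites, name="site"),
        ),
        skipped=list(skipped),
    )

    mo_cov = build_design(sub, "mediator_outcome", adjustment)
    X0 = np.column_stack([np.ones(n), e, mo_cov.to_numpy(dtype=float)])
    _check_full_rank(X0, ["intercept", "exposure", *mo_cov.columns])
    stats_beta = _ols_beta_sweep(X0, y, M, exposure_idx=1)
    beta = PathEstimates(
        path="mediator_outcome",
        table=pd.DataFrame(stats_beta, index=pd.Index(kept_sites, name="site")),
        skipped=list(skipped),
    )
    return alpha, beta


def fit_path(
    cohort: Cohort,
    path: str,
    site: str,
    outcome_domain: str = "cognitive",
    adjustment: AdjustmentSets | None = None,
    scale: str = "beta",
) -> pd.Series:
    """Fit one path model for one site; returns the site's estimate record."""
    if path not in ("exposure_mediator", "mediator_outcome"):
        raise ValueError(f"unknown path {path!r}")
    if site not in cohort.methylation.index:
        raise KeyError(f"unknown site {site!r}")
    m = _mediator_values(cohort, [site], scale)[:, 0]
    if m.var() == 0.0:
        raise DegenerateSiteError(f"site {site} has zero methylation variance")
    alpha, beta = fit_all_sites(
        cohort, outcome_domain=outcome_domain, adjustment=adjustment, scale=scale, sites=[site]
    )
    result = alpha if path == "exposure_mediator" else beta
    return result.table.loc[site]


def _subset_samples(cohort: Cohort, sample_ids) -> Cohort:
    return Cohort(
        methylation=cohort.methylation[list(sample_ids)],
        site_table=cohort.site_table,
        exposure=cohort.exposure.loc[sample_ids],
        outcomes=cohort.outcomes.loc[sample_ids],
        covariates=cohort.covariates.loc[sample_ids],
        gene_map=cohort.gene_map,
    )
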