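"""Synthetic birth-cohort generator for high-dimensional mediation analysis.

Emulates the statistical structure of an indoor-air-pollution / cord-blood
methylation / toddler-neurodevelopment study: a heavy-tailed positive exposure
(24-h PM10, µg/m³), a sites × samples matrix of methylation beta values with
block correlation and cell-type mixture structure, standardized developmental
composite scores across four domains, and the confounder set used by the
analysis models (SES, maternal smoking, alcohol, child sex, maternal age,
maternal HIV, genetic-ancestry scores, cell-type proportions).

A configurable subset of "planted" CpG sites truly mediates the
exposure→outcome effect: exposure shifts their latent (logit-scale) methylation
by ``alpha`` per µg/m³ and the primary outcome responds to their beta-value
methylation with slope ``beta`` (score points per methylation unit).  The
returned :class:`TruthSet` records the planted effects so that recovery can be
scored exactly.

Default calibration targets (study-characteristics table of the emulated
cohort): exposure mean 64.6, SD 96.8 µg/m³; cognitive composite mean 85.14,
SD 8.65; language 84.31 (12.22); motor 94.04 (13.74); adaptive 83.72 (13.29);
smoking non/passive/active = 26.8/40.1/33.1 %; alcohol 19.7 %; maternal HIV
21.1 %; female 40.1 %; SES 0.092 (2.25); maternal age 27.20 (5.98).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "Cohort",
    "TruthSet",
    "GeneMap",
    "generate_cohort",
    "assign_closest_gene",
    "beta_to_mvalue",
    "mvalue_to_beta",
]

#: outcome domains, primary first
DOMAINS = ("cognitive", "language", "motor", "adaptive")

_DOMAIN_MEANS = {"cognitive": 85.14, "language": 84.31, "motor": 94.04, "adaptive": 83.72}
_DOMAIN_SDS = {"cognitive": 8.65, "language": 12.22, "motor": 13.74, "adaptive": 13.29}

#: cord-blood-like 7-part cell composition (B, CD4T, CD8T, granulocytes,
#: monocytes, NK, nucleated RBC)
_CELLTYPE_BASE = np.array([0.05, 0.12, 0.08, 0.45, 0.08, 0.04, 0.18])
_CELLTYPE_NAMES = ("Bcell", "CD4T", "CD8T", "Gran", "Mono", "NK", "nRBC")


def beta_to_mvalue(beta: np.ndarray) -> np.ndarray:
    """Logit transform from methylation fraction (beta value) to M-value."""
    return logit(beta)


def mvalue_to_beta(m: np.ndarray) -> np.ndarray:
    """Inverse-logit transform from M-value back to a beta value in (0, 1)."""
    return expit(m)


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``alpha_effects`` are exposure→mediator slopes on the latent M-value
    (logit-beta) scale per µg/m³; ``beta_effects`` are mediator→outcome slopes
    in score points per unit beta-value methylation; ``direct_effect`` is the
    direct exposure→outcome slope in points per µg/m³.  With the default
    negative-mediation prior the planted sites have alpha > 0 and beta < 0,
    i.e. adverse mediation of the exposure on development.
    """

    n_samples: int = 142
    n_sites: int = 2000
    n_genes: int = 200
    sites_per_gene: int = 10
    n_planted: int = 0
    planted_per_gene: int = 1
    alpha_effects: np.ndarray | float = 0.004
    beta_effects: np.ndarray | float = -15.0
    direct_effect: float = -0.01
    exposure_mean: float = 64.6
    exposure_sd: float = 96.8
    outcome_mean: float = _DOMAIN_MEANS["cognitive"]
    outcome_sd: float = _DOMAIN_SDS["cognitive"]
    secondary_domains: bool = True
    block_size: int = 10
    block_rho: float = 0.3
    latent_noise_sd: float = 0.5
    n_celltypes: int = 7
    celltype_concentration: float = 60.0
    celltype_affected_fraction: float = 0.3
    celltype_loading_sd: float = 1.0
    # confounder -> (exposure slope, mediator loading SD, outcome slope).
    # Exposure slopes are on the log-exposure scale per standardized unit and
    # are folded into a fixed variance budget so the marginal exposure
    # calibration is exact.  Mediator loadings are per-site N(0, sd) draws on
    # the latent scale.
    confounder_effect_sizes: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "ses": (0.35, 0.05, 0.5),
            "smoking_active": (0.0, 0.08, -1.0),
            "sex_female": (0.0, 0.05, 1.0),
        }
    )
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_sites, self.n_genes, self.sites_per_gene) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.n_planted < 0 or self.n_planted > self.n_sites:
            raise ValueError("n_planted must lie in [0, n_sites]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")
        if self.exposure_sd <= 0 or self.outcome_sd <= 0:
            raise ValueError("exposure_sd and outcome_sd must be positive")
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        alpha = np.broadcast_to(np.asarray(self.alpha_effects, float), (self.n_planted,))
        beta = np.broadcast_to(np.asarray(self.beta_effects, float), (self.n_planted,))
        if self.n_planted and (np.any(alpha == 0) or np.any(beta == 0)):
            raise ValueError("planted sites must have nonzero alpha and beta")

    def planted_alpha(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.alpha_effects, float), (self.n_planted,)).copy()

    def planted_beta(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.beta_effects, float), (self.n_planted,)).copy()


@dataclass
class TruthSet:
    """Ground truth for the planted mediators (synthetic data only)."""

    table: pd.DataFrame  # index site, columns alpha, beta, nie
    direct_effect: float

    @property
    def planted_site_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneMap:
    """Gene intervals (0-based half-open) and the closest-gene site assignment."""

    genes: pd.DataFrame  # index gene, columns chrom, start, end
    assignment: pd.Series  # index site, value gene id (NaN when unassigned)

    def sites_for(self, gene: str) -> list[str]:
        return list(self.assignment.index[self.assignment == gene])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)


@dataclass
class Cohort:
    """One simulated cohort: methylation, exposure, outcomes, covariates."""

    methylation: pd.DataFrame  # sites × samples, beta values in (0, 1)
    site_table: pd.DataFrame  # index site, columns chrom, pos
    exposure: pd.Series  # per-sample PM10, µg/m³
    outcomes: pd.DataFrame  # samples × domains
    covariates: pd.DataFrame  # samples × covariate columns
    gene_map: GeneMap | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.exposure.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.methylation.index)

    @property
    def n_samples(self) -> int:
        return len(self.exposure)

    @property
    def celltype_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("ct_")]

    @property
    def ancestry_columns(self) -> list[str]:
        return [c for c in self.covariates.columns if c.startswith("ancestry")]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log scale hitting the requested arithmetic mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _gene_site_counts(n_sites: int, n_genes: int) -> np.ndarray:
    """Sites per gene; remainder spread one-per-gene from the first gene."""
    counts = np.full(n_genes, n_sites // n_genes, dtype=int)
    counts[: n_sites % n_genes] += 1
    if np.any(counts == 0):
        raise ValueError("more genes than sites: every gene needs >= 1 site")
    return counts


def generate_cohort(config: CohortConfig) -> tuple[Cohort, TruthSet]:
    """Generate one cohort and its planted-mediator truth set.

    Deterministic for a fixed ``config.seed``.  Mediators are built on a
    latent M-value scale as block-equicorrelated Gaussians shifted by per-site
    confounder loadings, cell-type mixture loadings and — for planted sites —
    ``alpha × centered exposure``; they are mapped to beta values through the
    logistic function, so every methylation value is strictly inside (0, 1).
    The primary outcome is linear in centered exposure (direct effect), the
    planted sites' beta-value methylation, and the confounders, plus Gaussian
    noise whose variance completes the configured outcome SD budget.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n, m = cfg.n_samples, cfg.n_sites

    sample_ids = [f"s{i:04d}" for i in range(n)]
    site_ids = [f"cg{i:07d}" for i in range(m)]

    # --- covariates -------------------------------------------------------
    ses_z = rng.standard_normal(n)
    ses = 0.092 + 2.25 * ses_z
    smoking = rng.choice(3, size=n, p=[0.268, 0.401, 0.331])  # 0 non, 1 passive, 2 active
    alcohol = (rng.random(n) < 0.197).astype(int)
    sex_female = (rng.random(n) < 0.401).astype(int)
    hiv = (rng.random(n) < 0.211).astype(int)
    maternal_age = 27.20 + 5.98 * rng.standard_normal(n)
    ancestry = rng.standard_normal((n, 5))
    celltypes = rng.dirichlet(cfg.celltype_concentration * _CELLTYPE_BASE[: cfg.n_celltypes]
                              / _CELLTYPE_BASE[: cfg.n_celltypes].sum(), size=n)

    conf_values = {
        "ses": ses_z,
        "smoking_passive": (smoking == 1).astype(float),
        "smoking_active": (smoking == 2).astype(float),
        "alcohol": alcohol.astype(float),
        "sex_female": sex_female.astype(float),
        "maternal_hiv": hiv.astype(float),
        "maternal_age": (maternal_age - 27.20) / 5.98,
    }

    # --- exposure ---------------------------------------------------------
    # log PM10 = mu + theta_ses * ses_z + resid; total log-scale variance is
    # held at the value implied by the target mean/SD so the marginal
    # calibration is exact for any confounding split.
    mu_log, sigma_log = _lognormal_params(cfg.exposure_mean, cfg.exposure_sd)
    theta = {k: v[0] for k, v in cfg.confounder_effect_sizes.items() if v[0] != 0.0}
    theta_total = float(np.sqrt(sum(t**2 for t in theta.values())))
    if theta_total >= sigma_log:
        raise ValueError("exposure confounding exceeds the log-scale variance budget")
    resid_sd = float(np.sqrt(sigma_log**2 - theta_total**2))
    log_e = mu_log + resid_sd * rng.standard_normal(n)
    for name, slope in theta.items():
        if name not in conf_values:
            raise ValueError(f"unknown confounder in config: {name}")
        log_e = log_e + slope * conf_values[name]
    exposure = np.exp(log_e)
    exposure_c = exposure - cfg.exposure_mean

    # --- latent methylation ----------------------------------------------
    # bimodal site baselines typical of array beta values
    comp = rng.choice(3, size=m, p=[0.35, 0.30, 0.35])
    mu_site = np.where(
        comp == 0,
        logit(0.08) + 0.5 * rng.standard_normal(m),
        np.where(comp == 1, 0.8 * rng.standard_normal(m), logit(0.92) + 0.5 * rng.standard_normal(m)),
    )

    # planted-site placement: planted_per_gene sites from each of the first
    # genes (1 per gene by default, so planted mediators occupy distinct
    # correlation blocks; raise it to concentrate signal for gene-level
    # tests).  Planted mediators live in the intermediate-methylation stratum:
    # sites pinned near 0 or 1 have almost no beta-scale variance and cannot
    # transmit a mediated effect.
    planted_idx = np.zeros(0, dtype=int)
    if cfg.n_planted:
        counts = _gene_site_counts(m, cfg.n_genes)
        gene_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        picks: list[int] = []
        g = 0
        while len(picks) < cfg.n_planted:
            if g >= cfg.n_genes:
                raise ValueError("not enough genes to place the planted sites")
            take = min(cfg.planted_per_gene, cfg.n_planted - len(picks), int(counts[g]))
            picks.extend(range(int(gene_starts[g]), int(gene_starts[g]) + take))
            g += 1
        planted_idx = np.asarray(picks[: cfg.n_planted])
        mu_site[planted_idx] = 0.8 * rng.standard_normal(cfg.n_planted)

    # block-equicorrelated noise; trailing partial block allowed
    n_blocks = -(-m // cfg.block_size)
    block_of = np.repeat(np.arange(n_blocks), cfg.block_size)[:m]
    shared = rng.standard_normal((n, n_blocks))[:, block_of]
    own = rng.standard_normal((n, m))
    noise = cfg.latent_noise_sd * (
        np.sqrt(cfg.block_rho) * shared + np.sqrt(1.0 - cfg.block_rho) * own
    )

    latent = mu_site[None, :] + noise
    # per-site confounder loadings, N(0, sd) so sign and magnitude vary by site
    for name, (_, med_sd, _) in cfg.confounder_effect_sizes.items():
        if med_sd != 0.0:
            loading = med_sd * rng.standard_normal(m)
            latent += np.outer(conf_values[name], loading)
    # cell-type mixture structure on a site subset
    n_affected = int(round(cfg.celltype_affected_fraction * m))
    if n_affected:
        affected = rng.choice(m, size=n_affected, replace=False)
        ct_load = cfg.celltype_loading_sd * rng.standard_normal((cfg.n_celltypes, n_affected))
        ct_centered = celltypes - _CELLTYPE_BASE[: cfg.n_celltypes] / _CELLTYPE_BASE[: cfg.n_celltypes].sum()
        latent[:, affected] += ct_centered @ ct_load

    # planted exposure effects on the latent scale
    if cfg.n_planted:
        alpha = cfg.planted_alpha()
        latent[:, planted_idx] += np.outer(exposure_c, alpha)

    methylation = expit(latent)

    # --- outcomes ---------------------------------------------------------
    beta_eff = cfg.planted_beta()
    conf_out = np.zeros(n)
    var_conf = 0.0
    for name, (_, _, out_slope) in cfg.confounder_effect_sizes.items():
        if out_slope != 0.0:
            v = conf_values[name]
            conf_out += out_slope * (v - v.mean())
            var_conf += out_slope**2 * v.var()
    if var_conf >= cfg.outcome_sd**2:
        raise ValueError("confounder outcome effects exceed the outcome SD budget")
    noise_sd = float(np.sqrt(cfg.outcome_sd**2 - var_conf))

    mediated = np.zeros(n)
    if cfg.n_planted:
        mplanted = methylation[:, planted_idx]
        mediated = (mplanted - mplanted.mean(axis=0)) @ beta_eff

    outcomes = {}
    primary = (
        cfg.outcome_mean
        + cfg.direct_effect * exposure_c
        + mediated
        + conf_out
        + noise_sd * rng.standard_normal(n)
    )
    outcomes["cognitive"] = primary
    if cfg.secondary_domains:
        for dom in DOMAINS[1:]:
            sd_dom = _DOMAIN_SDS[dom]
            scale = sd_dom / cfg.outcome_sd
            outcomes[dom] = (
                _DOMAIN_MEANS[dom]
                + scale * conf_out
                + float(np.sqrt(sd_dom**2 - scale**2 * var_conf)) * rng.standard_normal(n)
            )

    # --- genome layout ----------------------------------------------------
    counts = _gene_site_counts(m, cfg.n_genes)
    chroms, starts, ends, gene_ids = [], [], [], []
    site_chrom = np.empty(m, dtype=object)
    site_pos = np.empty(m, dtype=int)
    genes_per_chrom = -(-cfg.n_genes // 22)
    cursor, idx = 10_000, 0
    for g in range(cfg.n_genes):
        chrom = f"chr{g // genes_per_chrom + 1}"
        if g % genes_per_chrom == 0:
            cursor = 10_000
        length = int(2_000 + 8_000 * rng.random())
        start, end = cursor, cursor + length
        gene_ids.append(f"gene{g:04d}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        pos = np.sort(rng.integers(start, end, size=counts[g]))
        for p in pos:
            site_chrom[idx] = chrom
            site_pos[idx] = p
            idx += 1
        cursor = end + int(5_000 + 20_000 * rng.random())

    site_table = pd.DataFrame({"chrom": site_chrom, "pos": site_pos}, index=pd.Index(site_ids, name="site"))
    genes = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends},
        index=pd.Index(gene_ids, name="gene"),
    )
    gene_map = assign_closest_gene(site_table, genes)

    covariates = pd.DataFrame(
        {
            "ses": ses,
            "smoking": smoking,
            "alcohol": alcohol,
            "sex_female": sex_female,
            "maternal_age": maternal_age,
            "maternal_hiv": hiv,
            **{f"ancestry{i + 1}": ancestry[:, i] for i in range(5)},
            **{f"ct_{_CELLTYPE_NAMES[i]}": celltypes[:, i] for i in range(cfg.n_celltypes)},
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    meth = pd.DataFrame(methylation.T, index=site_table.index, columns=sample_ids)
    outcome_df = pd.DataFrame(outcomes, index=pd.Index(sample_ids, name="sample"))

    if cfg.missing_fraction > 0.0:
        mask = rng.random(outcome_df.shape) < cfg.missing_fraction
        outcome_df = outcome_df.mask(mask)

    cohort = Cohort(
        methylation=meth,
        site_table=site_table,
        exposure=pd.Series(exposure, index=covariates.index, name="pm10"),
        outcomes=outcome_df,
        covariates=covariates,
        gene_map=gene_map,
    )

    alpha = cfg.planted_alpha()
    truth = TruthSet(
        table=pd.DataFrame(
            {"alpha": alpha, "beta": beta_eff, "nie": alpha * beta_eff},
            index=pd.Index([site_ids[i] for i in planted_idx], name="site"),
        ),
        direct_effect=cfg.direct_effect,
    )
    return cohort, truth


def assign_closest_gene(site_table: pd.DataFrame, gene_intervals: pd.DataFrame) -> GeneMap:
    """Annotate every site with its closest gene.

    Distance is 0 for a site inside the half-open interval [start, end);
    otherwise max(start - pos, pos - end), the gap to the nearer interval
    boundary (so a site 50 bp left of one gene and 50 bp right of another is
    genuinely equidistant).  Ties are broken
    by the lower interval start (then by gene id), which makes the assignment
    deterministic and independent of input order.  Sites on chromosomes with
    no gene are flagged unassigned (NaN), never dropped.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(gene_intervals.columns):
        raise ValueError("gene_intervals needs chrom/start/end columns")
    if np.any(gene_intervals["end"].to_numpy() <= gene_intervals["start"].to_numpy()):
        raise ValueError("degenerate gene interval (end <= start)")

    assignment = pd.Series(np.nan, index=site_table.index, dtype=object, name="gene")
    for chrom, sites in site_table.groupby("chrom", sort=False):
        genes = gene_intervals[gene_intervals["chrom"] == chrom]
        if genes.empty:
            logger.warning("no genes on %s: %d sites left unassigned", chrom, len(sites))
            continue
        pos = sites["pos"].to_numpy()[:, None]
        start = genes["start"].to_numpy()[None, :]
        end = genes["end"].to_numpy()[None, :]
        dist = np.maximum.reduce([start - pos, pos - end, np.zeros_like(pos - start)])
        # lexicographic tie-break: distance, then interval start, then gene id
        order = np.lexsort((genes.index.to_numpy(), genes["start"].to_numpy()))
        dist = dist[:, order]
        best = np.argmin(dist, axis=1)  # argmin keeps the first = lowest start
        assignment.loc[sites.index] = genes.index.to_numpy()[order][best]
    return GeneMap(genes=gene_intervals.copy(), assignment=assignment)


def null_config(**overrides) -> CohortConfig:
    """A fully null configuration (no planted mediation, no direct effect)."""
    base = CohortConfig(n_planted=0, direct_effect=0.0)
    return replace(base, **overrides)
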