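"""Config-driven orchestration of the full mediation workflow.

Stages, per outcome domain: dual-path association sweep → dual-path
pre-screen (feeding DACT) and SIS (feeding HIMA) → DACT and HIMA at site
level, gHMA at gene level → quasi-Bayesian causal-mediation validation of the
FDR survivors (union of DACT and HIMA calls plus any explicitly listed
sites).  Every run writes its result tables and a JSON manifest with per-stage
record counts and warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AdjustmentSets, fit_all_sites
from .cohort import Cohort, CohortConfig, TruthSet, generate_cohort
from .dact import run_dact
from .diagnostics import pearson_matrix
from .ghma import run_ghma
from .hima import McpConfig, run_hima
from .mediation import estimates_table, mediate_candidates
from .screening import prescreen, sis_screen
from . import io as eio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    input_mode: str = "synthetic"  # "synthetic" | "files"
    methylation_path: str | None = None
    phenotype_path: str | None = None
    site_path: str | None = None
    gene_path: str | None = None
    domains: tuple[str, ...] = ("cognitive",)
    include_hiv: bool = False
    n_celltype_pcs: int = 3
    n_ancestry_pcs: int = 5
    scale: str = "beta"
    enable_dact: bool = True
    enable_hima: bool = True
    enable_ghma: bool = True
    enable_mediation: bool = True
    prescreen_p_threshold: float = 0.05
    prescreen_direction: str = "negative"
    sis_d: int | None = None
    mcp_gamma: float = 3.0
    mcp_selection_rule: str = "bic"
    ghma_omnibus: str = "cauchy"
    mediation_draws: int = 1000
    extra_mediation_sites: tuple[str, ...] = ()
    include_nominal_hima: bool = False
    fdr_q: float = 0.05
    seed: int | None = None
    outdir: str = "epimediate_run"
    synthetic: dict = field(default_factory=dict)  # CohortConfig overrides

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValueError("input_mode must be 'synthetic' or 'files'")
        if not (self.enable_dact or self.enable_hima or self.enable_ghma):
            raise ValueError("at least one method must be enabled")
        if not self.domains:
            raise ValueError("at least one outcome domain is required")
        if self.input_mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory for synthetic input")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "domains" in raw:
            raw["domains"] = tuple(raw["domains"])
        if "extra_mediation_sites" in raw:
            raw["extra_mediation_sites"] = tuple(raw["extra_mediation_sites"])
        return cls(**raw)

    def adjustment(self) -> AdjustmentSets:
        return AdjustmentSets(
            include_hiv=self.include_hiv,
            n_celltype_pcs=self.n_celltype_pcs,
            n_ancestry_pcs=self.n_ancestry_pcs,
        )


def _load_cohort(config: PipelineConfig) -> tuple[Cohort, TruthSet | None]:
    if config.input_mode == "synthetic":
        overrides = dict(config.synthetic)
        overrides.setdefault("seed", config.seed)
        cohort, truth = generate_cohort(CohortConfig(**overrides))
        return cohort, truth
    cohort = eio.read_cohort(
        config.methylation_path, config.phenotype_path, config.site_path, config.gene_path
    )
    return cohort, None


def validate_inputs(methylation_path, phenotype_path, site_path=None, gene_path=None) -> list[dict]:
    """Input sanity report: every failure is an entry, an empty list is a pass."""
    failures: list[dict] = []
    meth = eio.read_methylation(methylation_path)
    pheno = eio.read_phenotypes(phenotype_path)
    missing = [s for s in meth.columns if s not in pheno.index]
    for s in missing:
        failures.append({"check": "sample_id_agreement", "detail": f"sample {s} absent from phenotype table"})
    vals = meth.to_numpy(dtype=float)
    bad = ~((vals > 0.0) & (vals < 1.0))
    if bad.any():
        idx = np.argwhere(bad)[0]
        failures.append({
            "check": "beta_range",
            "detail": f"{int(bad.sum())} methylation value(s) outside (0,1), "
                      f"first at site {meth.index[idx[0]]} sample {meth.columns[idx[1]]}",
        })
    covar_cols = [c for c in pheno.columns if c not in ("cognitive", "language", "motor", "adaptive")]
    n_incomplete = int(pheno[covar_cols].isna().any(axis=1).sum())
    if n_incomplete:
        failures.append({"check": "covariate_completeness",
                         "detail": f"{n_incomplete} sample(s) with missing covariates (complete-case rule drops them)"})
    if site_path:
        sites = eio.read_site_table(site_path)
        absent = [s for s in meth.index if s not in sites.index]
        if absent:
            failures.append({"check": "site_table", "detail": f"{len(absent)} matrix site(s) missing positions"})
    if gene_path:
        genes = eio.read_gene_bed(gene_path)
        if (genes["end"] <= genes["start"]).any():
            failures.append({"check": "gene_intervals", "detail": "degenerate interval (end <= start)"})
    return failures


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the run manifest (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "version": __version__,
        "stages": [],
        "warnings": [],
        "files": {},
        "domains": {},
    }

    cohort, truth = _load_cohort(config)
    # complete-case rule on covariates
    n_before = cohort.n_samples
    complete = cohort.covariates.notna().all(axis=1) & cohort.exposure.notna()
    if not complete.all():
        from .association import _subset_samples
        cohort = _subset_samples(cohort, complete.index[complete])
        manifest["warnings"].append(
            f"complete-case rule dropped {int((~complete).sum())} of {n_before} samples"
        )
    manifest["stages"].append({"stage": "load", "n_samples": cohort.n_samples,
                               "n_sites": len(cohort.site_ids)})
    if truth is not None:
        eio.write_truth(outdir / "truth.tsv", truth)
        manifest["files"]["truth"] = "truth.tsv"

    adjustment = config.adjustment()
    rng_seed = config.seed if config.seed is not None else 0

    for domain in config.domains:
        if domain not in cohort.outcomes.columns:
            raise ValueError(f"stage association ({domain}): outcome domain missing")
        dom_dir = outdir / domain
        dom_dir.mkdir(exist_ok=True)
        dom_record: dict = {}

        try:
            alpha_est, beta_est = fit_all_sites(
                cohort, outcome_domain=domain, adjustment=adjustment, scale=config.scale
            )
        except Exception as exc:  # abort with the stage name, keep partial manifest
            manifest["stages"].append({"stage": f"association:{domain}", "error": str(exc)})
            _write_manifest(outdir, manifest)
            raise
        for est, name in ((alpha_est, "alpha"), (beta_est, "beta")):
            f = dom_dir / f"path_{name}.tsv"
            est.table.to_csv(f, sep="\t", float_format=eio.FLOAT_FMT)
            manifest["files"][f"{domain}/path_{name}"] = str(f.relative_to(outdir))
        dom_record["n_tested_sites"] = len(alpha_est.table)
        dom_record["n_degenerate_sites"] = len(alpha_est.skipped)
        if alpha_est.skipped:
            manifest["warnings"].append(f"{domain}: {len(alpha_est.skipped)} degenerate site(s) skipped")

        survivors: set[str] = set(config.extra_mediation_sites)

        if config.enable_dact:
            screen = prescreen(alpha_est, beta_est, p_threshold=config.prescreen_p_threshold,
                               direction=config.prescreen_direction)
            screen.reasons.to_csv(dom_dir / "screen.tsv", sep="\t")
            dom_record["n_screened"] = len(screen)
            if len(screen):
                dact = run_dact(alpha_est, beta_est, screen, fdr_q=config.fdr_q)
                dact.table.to_csv(dom_dir / "dact.tsv", sep="\t", float_format=eio.FLOAT_FMT)
                with open(dom_dir / "dact_run.json", "w") as fh:
                    json.dump({"delta": dact.delta, "sigma": dact.sigma,
                               "calibrated": dact.calibrated,
                               "weights": asdict(dact.weights),
                               "p_threshold": screen.p_threshold,
                               "direction": screen.direction}, fh, indent=2)
                if not dact.calibrated:
                    manifest["warnings"].append(f"{domain}: DACT calibration skipped (screened set < 100)")
                dact_hits = dact.significant_sites(config.fdr_q)
                dom_record["n_dact_significant"] = len(dact_hits)
                survivors |= set(dact_hits)
            else:
                manifest["warnings"].append(f"{domain}: empty pre-screen, DACT skipped")
                dom_record["n_dact_significant"] = 0

        if config.enable_hima:
            candidates = sis_screen(beta_est, cohort.n_samples, d=config.sis_d)
            dom_record["n_sis_candidates"] = len(candidates)
            hima = run_hima(
                cohort, outcome_domain=domain, adjustment=adjustment,
                sis_candidates=candidates,
                config=McpConfig(gamma=config.mcp_gamma, selection_rule=config.mcp_selection_rule),
                fdr_q=config.fdr_q, scale=config.scale,
            )
            hima.table.to_csv(dom_dir / "hima.tsv", sep="\t", float_format=eio.FLOAT_FMT)
            hima_hits = hima.significant_sites(config.fdr_q)
            dom_record["n_hima_selected"] = len(hima.table)
            dom_record["n_hima_significant"] = len(hima_hits)
            survivors |= set(hima_hits)
            if config.include_nominal_hima:
                survivors |= set(hima.table.index[hima.table["joint_p"] < 0.05])

        if config.enable_ghma:
            if cohort.gene_map is None:
                manifest["warnings"].append(f"{domain}: no gene map, gHMA skipped")
            else:
                ghma = run_ghma(cohort, outcome_domain=domain, adjustment=adjustment,
                                fdr_q=config.fdr_q, scale=config.scale,
                                omnibus_method=config.ghma_omnibus)
                ghma.table.to_csv(dom_dir / "ghma.tsv", sep="\t", float_format=eio.FLOAT_FMT)
                dom_record["n_genes_tested"] = len(ghma.table)
                dom_record["n_genes_degenerate"] = len(ghma.degenerate_genes)
                dom_record["n_ghma_significant"] = len(ghma.significant_genes(config.fdr_q))

        if config.enable_mediation:
            candidates = sorted(s for s in survivors if s in cohort.methylation.index)
            dom_record["n_mediation_candidates"] = len(candidates)
            if len(candidates) >= 2:
                # neither site-level method accounts for mediator correlation;
                # report it alongside the estimates
                corr = pearson_matrix(cohort.methylation.loc[candidates])
                corr.to_csv(dom_dir / "mediator_correlations.tsv", sep="\t",
                            float_format=eio.FLOAT_FMT)
            domain_key = zlib.crc32(domain.encode()) % (2**31)
            med_seed = int(np.random.SeedSequence([rng_seed, domain_key]).generate_state(1)[0] % (2**31))
            estimates = mediate_candidates(
                cohort, candidates, outcome_domain=domain, adjustment=adjustment,
                n_draws=config.mediation_draws, seed=med_seed, scale=config.scale,
                iqr_scale=True,
            )
            table = estimates_table(estimates)
            table.to_csv(dom_dir / "mediation.tsv", sep="\t", float_format=eio.FLOAT_FMT)
            dom_record["n_mediation_validated"] = sum(
                1 for e in estimates if e.nie_significant and e.te_significant
            )

        manifest["domains"][domain] = dom_record
        manifest["stages"].append({"stage": f"domain:{domain}", **dom_record})

    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
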