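"""Plain-text readers and writers for cohort and result tables.

All writers emit tab-separated text with floats at 12 significant digits, so a
write/read round trip reproduces values to that precision.  The methylation
matrix is sites × samples with the site id in the first column; phenotypes are
one row per sample; gene intervals use a 4-column BED-like layout (chrom,
start, end, gene; 0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, GeneMap, TruthSet, assign_closest_gene

FLOAT_FMT = "%.12g"

__all__ = [
    "write_methylation", "read_methylation",
    "write_phenotypes", "read_phenotypes",
    "write_site_table", "read_site_table",
    "write_gene_bed", "read_gene_bed",
    "write_truth", "read_truth",
    "write_cohort", "read_cohort",
]


def write_methylation(path, methylation: pd.DataFrame) -> None:
    methylation.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="site")


def read_methylation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")


def write_phenotypes(path, cohort: Cohort) -> None:
    pheno = pd.concat([cohort.exposure.rename("pm10"), cohort.outcomes, cohort.covariates], axis=1)
    pheno.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="sample")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_site_table(path, site_table: pd.DataFrame) -> None:
    site_table.to_csv(path, sep="\t", index_label="site")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")


def write_gene_bed(path, genes: pd.DataFrame) -> None:
    bed = genes.reset_index()[["chrom", "start", "end", genes.index.name or "gene"]]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "gene"])
    return bed.set_index("gene")


def write_truth(path, truth: TruthSet) -> None:
    tab = truth.table.copy()
    tab["direct_effect"] = truth.direct_effect
    tab.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="site")


def read_truth(path) -> TruthSet:
    tab = pd.read_csv(path, sep="\t", index_col="site")
    direct = float(tab["direct_effect"].iloc[0]) if len(tab) else 0.0
    return TruthSet(table=tab.drop(columns=["direct_effect"]), direct_effect=direct)


def write_cohort(outdir, cohort: Cohort, truth: TruthSet | None = None) -> dict[str, str]:
    """Write a full cohort (and optional truth set); returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "methylation": str(outdir / "methylation.tsv"),
        "phenotypes": str(outdir / "phenotypes.tsv"),
        "sites": str(outdir / "sites.tsv"),
        "genes": str(outdir / "genes.bed"),
    }
    write_methylation(files["methylation"], cohort.methylation)
    write_phenotypes(files["phenotypes"], cohort)
    write_site_table(files["sites"], cohort.site_table)
    if cohort.gene_map is not None:
        write_gene_bed(files["genes"], cohort.gene_map.genes)
    if truth is not None:
        files["truth"] = str(outdir / "truth.tsv")
        write_truth(files["truth"], truth)
    return files


def read_cohort(methylation_path, phenotype_path, site_path=None, gene_path=None) -> Cohort:
    """Assemble a Cohort from TSV inputs (samples aligned on shared ids)."""
    meth = read_methylation(methylation_path)
    pheno = read_phenotypes(phenotype_path)
    common = [s for s in meth.columns if s in pheno.index]
    if not common:
        raise ValueError("no samples shared between methylation matrix and phenotype table")
    meth = meth[common]
    pheno = pheno.loc[common]
    outcome_cols = [c for c in ("cognitive", "language", "motor", "adaptive") if c in pheno.columns]
    covar_cols = [c for c in pheno.columns if c not in outcome_cols + ["pm10"]]
    site_table = read_site_table(site_path) if site_path else pd.DataFrame(
        {"chrom": "chrUn", "pos": np.arange(len(meth))}, index=meth.index
    )
    gene_map = None
    if gene_path:
        genes = read_gene_bed(gene_path)
        gene_map = assign_closest_gene(site_table, genes)
    return Cohort(
        methylation=meth,
        site_table=site_table,
        exposure=pheno["pm10"],
        outcomes=pheno[outcome_cols],
        covariates=pheno[covar_cols],
        gene_map=gene_map,
    )
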