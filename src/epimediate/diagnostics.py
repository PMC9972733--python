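"""Shared statistical utilities: BH FDR, mediator correlations, calibration checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FdrTable", "bh_fdr", "pearson_matrix", "ks_uniformity"]


@dataclass
class FdrTable:
    table: pd.DataFrame  # columns p, p_adjusted, significant
    q: float

    @property
    def significant_ids(self) -> list:
        return list(self.table.index[self.table["significant"]])


def bh_fdr(p, q: float = 0.05, ids=None) -> FdrTable:
    """Benjamini–Hochberg step-up adjustment.

    adjusted_i = min_{j >= i} (m * p_(j) / j), clipped at 1, mapped back to
    input order; the suffix-minimum formulation is stable under ties.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    idx = ids if ids is not None else pd.RangeIndex(m)
    if m == 0:
        empty = pd.DataFrame({"p": [], "p_adjusted": [], "significant": []})
        return FdrTable(table=empty, q=q)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, None, 1.0)
    table = pd.DataFrame(
        {"p": p, "p_adjusted": adjusted, "significant": adjusted <= q},
        index=pd.Index(idx),
    )
    return FdrTable(table=table, q=q)


def pearson_matrix(methylation: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among selected sites (rows = sites, cols = samples)."""
    if methylation.shape[0] < 2:
        raise ValueError("need at least 2 sites for a correlation matrix")
    values = methylation.to_numpy(dtype=float)
    sds = values.std(axis=1)
    zero = methylation.index[sds == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance site(s): {list(zero)}")
    corr = np.corrcoef(values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=methylation.index, columns=methylation.index)


def ks_uniformity(p) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov test of p-values against Uniform(0, 1)."""
    p = np.asarray(p, dtype=float)
    if p.size < 20:
        raise ValueError("need at least 20 p-values for a meaningful KS check")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("values outside [0, 1]")
    res = stats.kstest(p, "uniform", mode="asymp")
    return float(res.statistic), float(res.pvalue)
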