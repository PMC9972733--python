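"""Penalized high-dimensional mediation (SIS + MCP + joint significance).

Candidates from sure independence screening enter one joint outcome model in
which exposure and confounders are unpenalized and the mediators carry a
minimax concave penalty (MCP).  The MCP is nearly unbiased for large
coefficients: on a standardized column it acts as the firm-thresholding
operator

    b(z) = 0                          |z| <= lambda
    b(z) = sign(z)(|z|-lambda)/(1-1/gamma)   lambda < |z| <= gamma*lambda
    b(z) = z                          |z| > gamma*lambda

applied coordinate-wise within a descent loop with warm starts along a
decreasing lambda grid.  Mediators selected at the information-criterion
optimum are refit without penalty for mediator→outcome p-values, paired with
their exposure→mediator p-values, and judged by the joint-significance rule
p = max(p_alpha, p_beta) with BH FDR over the selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .association import AdjustmentSets, build_design, fit_all_sites
from .cohort import Cohort
from .diagnostics import bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["McpConfig", "HimaResult", "McpPath", "mcp_fit", "run_hima"]


@dataclass
class McpConfig:
    gamma: float = 3.0
    lambda_path: np.ndarray | str = "auto"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.05
    selection_rule: str = "bic"
    ebic_gamma: float = 0.5
    max_iter: int = 10_000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise ValueError("MCP concavity gamma must exceed 1")
        if self.tol <= 0.0:
            raise ValueError("tol must be positive")
        if self.selection_rule not in ("bic", "ebic"):
            raise ValueError("selection_rule must be 'bic' or 'ebic'")
        if isinstance(self.lambda_path, (list, tuple, np.ndarray)):
            lam = np.asarray(self.lambda_path, dtype=float)
            if lam.size > 1 and np.any(np.diff(lam) >= 0):
                raise ValueError("lambda grid must be strictly decreasing")
            self.lambda_path = lam


@dataclass
class McpPath:
    """Solution path of one MCP fit, on the original predictor scale."""

    lambdas: np.ndarray
    coefs: np.ndarray  # p × n_lambda
    intercepts: np.ndarray
    rss: np.ndarray
    n_iter: np.ndarray


@dataclass
class HimaResult:
    table: pd.DataFrame  # site-indexed: alpha, p_alpha, beta, p_beta, joint_p, fdr, nie
    selected_lambda: float | None
    n_candidates: int
    metadata: dict = field(default_factory=dict)

    def significant_sites(self, q: float = 0.05) -> list[str]:
        if self.table.empty:
            return []
        return list(self.table.index[self.table["fdr"] <= q])


def _firm_threshold(z: float, lam: float, gamma: float) -> float:
    az = abs(z)
    if az <= lam:
        return 0.0
    if az <= gamma * lam:
        return np.sign(z) * (az - lam) / (1.0 - 1.0 / gamma)
    return z


@numba.njit(cache=False)
def _penalized_sweep(Xt, r, b, lam, gamma):  # pragma: no cover - jitted
    """One full coordinate-descent sweep over the penalized block (Xt: p × n)."""
    p, n = Xt.shape
    max_change = 0.0
    for j in range(p):
        z = 0.0
        for i in range(n):
            z += Xt[j, i] * r[i]
        z = z / n + b[j]
        az = abs(z)
        if az <= lam:
            bj = 0.0
        elif az <= gamma * lam:
            s = 1.0 if z > 0 else -1.0
            bj = s * (az - lam) / (1.0 - 1.0 / gamma)
        else:
            bj = z
        d = bj - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * Xt[j, i]
            if abs(d) > max_change:
                max_change = abs(d)
            b[j] = bj
    return max_change


def mcp_fit(response, design, unpenalized_columns, config: McpConfig | None = None) -> McpPath:
    """MCP-penalized least squares by coordinate descent with warm starts.

    ``design`` columns indexed by ``unpenalized_columns`` are never
    thresholded (they take plain least-squares updates).  All columns are
    standardized internally to unit variance (and the response centered); the
    returned coefficients and intercepts are on the original scale.
    """
    config = config or McpConfig()
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    unpen = np.zeros(p, dtype=bool)
    unpen[list(unpenalized_columns)] = True

    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    if np.any(sd_x == 0.0):
        raise ValueError("zero-variance design column(s): standardization impossible")
    Xs = (X - mu_x) / sd_x
    ybar = y.mean()
    yc = y - ybar

    if isinstance(config.lambda_path, str):
        # residual of y on the unpenalized block sets the entry point
        if unpen.any():
            U = Xs[:, unpen]
            r0 = yc - U @ np.linalg.lstsq(U, yc, rcond=None)[0]
        else:
            r0 = yc
        pen_cols = Xs[:, ~unpen]
        lam_max = np.abs(pen_cols.T @ r0).max() / n if pen_cols.size else 1.0
        lam_max = max(lam_max, 1e-12)
        lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)
    else:
        lambdas = np.asarray(config.lambda_path, dtype=float)

    b = np.zeros(p)
    coefs = np.zeros((p, lambdas.size))
    rss = np.zeros(lambdas.size)
    iters = np.zeros(lambdas.size, dtype=int)

    pen_idx = np.array([j for j in range(p) if not unpen[j]], dtype=int)
    unpen_idx = np.array([j for j in range(p) if unpen[j]], dtype=int)
    U = Xs[:, unpen_idx] if unpen_idx.size else np.empty((n, 0))
    # the unpenalized block is solved exactly (block descent via a cached QR)
    # instead of coordinate-wise: correlated covariates make plain coordinate
    # updates converge very slowly, while the fixed point is identical
    Uq, Ur = (np.linalg.qr(U) if unpen_idx.size else (None, None))
    Xt_pen = np.ascontiguousarray(Xs[:, pen_idx].T)
    r = yc.copy()
    b_pen = np.zeros(pen_idx.size)

    def solve_unpen():
        nonlocal r
        if not unpen_idx.size:
            return 0.0
        r_wo = r + U @ b[unpen_idx]
        new = np.linalg.solve(Ur, Uq.T @ r_wo)
        change = float(np.max(np.abs(new - b[unpen_idx])))
        r = r_wo - U @ new
        b[unpen_idx] = new
        return change

    for li, lam in enumerate(lambdas):
        for it in range(config.max_iter):
            change = solve_unpen()
            change = max(change, _penalized_sweep(Xt_pen, r, b_pen,
                                                  float(lam), float(config.gamma)))
            if change < config.tol:
                break
        else:
            raise RuntimeError(
                f"MCP coordinate descent failed to converge at lambda index {li} "
                f"(lambda={lam:.4g}, max_iter={config.max_iter})"
            )
        b[pen_idx] = b_pen
        coefs[:, li] = b
        rss[li] = r @ r
        iters[li] = it + 1

    coefs_orig = coefs / sd_x[:, None]
    intercepts = ybar - mu_x @ coefs_orig
    return McpPath(lambdas=lambdas, coefs=coefs_orig, intercepts=intercepts,
                   rss=rss, n_iter=iters)


def _information_criterion(path: McpPath, n: int, p_pen: int, pen_mask: np.ndarray,
                           rule: str, ebic_gamma: float) -> np.ndarray:
    k_total = (path.coefs != 0).sum(axis=0) + 1  # + intercept
    ic = n * np.log(np.maximum(path.rss, 1e-300) / n) + k_total * np.log(n)
    if rule == "ebic":
        k_pen = (path.coefs[pen_mask] != 0).sum(axis=0)
        log_binom = np.array([
            lgamma(p_pen + 1) - lgamma(k + 1) - lgamma(p_pen - k + 1) for k in k_pen
        ])
        ic = ic + 2.0 * ebic_gamma * log_binom
    return ic


def run_hima(
    cohort: Cohort,
    outcome_domain: str = "cognitive",
    adjustment: AdjustmentSets | None = None,
    sis_candidates: list[str] | None = None,
    config: McpConfig | None = None,
    fdr_q: float = 0.05,
    scale: str = "beta",
) -> HimaResult:
    """Joint MCP outcome model over the SIS candidates, then joint significance.

    Exposure and the mediator–outcome covariates enter unpenalized; the
    candidate mediators are penalized.  Mediators with nonzero coefficients at
    the information-criterion-optimal lambda are refit by plain OLS for
    mediator→outcome p-values; their exposure→mediator p-values come from the
    covariate-adjusted alpha-path model; mediation is judged by
    p = max(p_alpha, p_beta) with BH FDR over the selected set.  An empty
    selection is a valid outcome and yields an empty table.
    """
    if not sis_candidates:
        raise ValueError("sis_candidates must be non-empty")
    adjustment = adjustment or AdjustmentSets()
    config = config or McpConfig()

    y_all = cohort.outcomes[outcome_domain]
    keep = y_all.notna()
    samples = y_all.index[keep]
    y = y_all.loc[samples].to_numpy(dtype=float)
    n = len(y)

    from .association import _mediator_values, _subset_samples  # shared internals

    sub = cohort if keep.all() else _subset_samples(cohort, samples)
    cov = build_design(sub, "mediator_outcome", adjustment)
    U = np.column_stack([sub.exposure.to_numpy(dtype=float), cov.to_numpy(dtype=float)])
    M = _mediator_values(sub, sis_candidates, scale)
    X = np.column_stack([U, M])
    n_unpen = U.shape[1]

    path = mcp_fit(y, X, unpenalized_columns=range(n_unpen), config=config)
    ic = _information_criterion(
        path, n, p_pen=len(sis_candidates),
        pen_mask=np.arange(X.shape[1]) >= n_unpen,
        rule=config.selection_rule, ebic_gamma=config.ebic_gamma,
    )
    best = int(np.argmin(ic))
    lam = float(path.lambdas[best])
    pen_coefs = path.coefs[n_unpen:, best]
    selected = [s for s, c in zip(sis_candidates, pen_coefs) if c != 0.0]
    meta = {
        "selection_rule": config.selection_rule,
        "n_candidates": len(sis_candidates),
        "note": "p_beta from unpenalized post-selection refit; inference is conditional on selection",
    }
    if not selected:
        logger.info("MCP selected no mediators at the %s optimum", config.selection_rule)
        empty = pd.DataFrame(
            columns=["alpha", "p_alpha", "beta", "p_beta", "joint_p", "fdr", "nie"],
            index=pd.Index([], name="site"),
        )
        return HimaResult(table=empty, selected_lambda=lam,
                          n_candidates=len(sis_candidates), metadata=meta)

    # unpenalized joint refit on the selected mediators
    Msel = _mediator_values(sub, selected, scale)
    Xr = np.column_stack([np.ones(n), U, Msel])
    coef, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    resid = y - Xr @ coef
    df = n - Xr.shape[1]
    sigma2 = resid @ resid / df
    G = np.linalg.inv(Xr.T @ Xr)
    se = np.sqrt(sigma2 * np.diag(G))
    b_med = coef[1 + n_unpen:]
    se_med = se[1 + n_unpen:]
    p_beta = 2.0 * stats.t.sf(np.abs(b_med / se_med), df)

    alpha_est, _ = fit_all_sites(sub, outcome_domain=outcome_domain,
                                 adjustment=adjustment, scale=scale, sites=selected)
    a = alpha_est.table.loc[selected]
    joint_p = np.maximum(a["p"].to_numpy(), p_beta)
    fdr = bh_fdr(joint_p, q=fdr_q, ids=pd.Index(selected, name="site"))
    table = pd.DataFrame(
        {
            "alpha": a["estimate"].to_numpy(),
            "p_alpha": a["p"].to_numpy(),
            "beta": b_med,
            "p_beta": p_beta,
            "joint_p": joint_p,
            "fdr": fdr.table["p_adjusted"].to_numpy(),
            "nie": a["estimate"].to_numpy() * b_med,
        },
        index=pd.Index(selected, name="site"),
    )
    return HimaResult(table=table, selected_lambda=lam,
                      n_candidates=len(sis_candidates), metadata=meta)
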