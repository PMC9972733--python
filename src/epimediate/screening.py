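"""Candidate-reduction rules ahead of the composite-null and penalized tests.

Two screens are provided: a dual-path p-value pre-screen with a directional
filter on the implied indirect effect (feeding the composite-null DACT test),
and sure independence screening (SIS) by marginal mediator→outcome association
strength (feeding the MCP-penalized model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .association import PathEstimates

__all__ = ["ScreenSet", "prescreen", "sis_screen", "default_sis_size"]


@dataclass
class ScreenSet:
    """Outcome of the dual-path pre-screen with a full audit trail."""

    retained: list[str]
    reasons: pd.DataFrame  # index site; boolean columns p_alpha_fail, p_beta_fail, direction_fail
    p_threshold: float
    direction: str

    @property
    def excluded(self) -> list[str]:
        return [s for s in self.reasons.index if s not in set(self.retained)]

    def __len__(self) -> int:
        return len(self.retained)


def prescreen(
    alpha_est: PathEstimates,
    beta_est: PathEstimates,
    p_threshold: float = 0.05,
    direction: str = "negative",
) -> ScreenSet:
    """Retain sites nominally associated with both exposure and outcome.

    A site survives iff p_alpha < threshold, p_beta < threshold and the sign
    of the implied indirect effect alpha*beta matches ``direction``
    ("negative", "positive", or "any" to disable the sign rule).  Every
    excluded site carries at least one reason code.
    """
    if direction not in ("negative", "positive", "any"):
        raise ValueError("direction must be 'negative', 'positive' or 'any'")
    a, b = alpha_est.table, beta_est.table
    if set(a.index) != set(b.index):
        raise ValueError("alpha and beta estimates cover different site universes")
    b = b.reindex(a.index)

    p_alpha_fail = ~(a["p"] < p_threshold)
    p_beta_fail = ~(b["p"] < p_threshold)
    nie_sign = a["estimate"] * b["estimate"]
    if direction == "negative":
        direction_fail = ~(nie_sign < 0)
    elif direction == "positive":
        direction_fail = ~(nie_sign > 0)
    else:
        direction_fail = pd.Series(False, index=a.index)

    reasons = pd.DataFrame(
        {
            "p_alpha_fail": p_alpha_fail,
            "p_beta_fail": p_beta_fail,
            "direction_fail": direction_fail,
        }
    )
    retained = list(a.index[~reasons.any(axis=1)])
    return ScreenSet(retained=retained, reasons=reasons, p_threshold=p_threshold, direction=direction)


def default_sis_size(n_samples: int) -> int:
    """The screening-size convention d = floor(2n / ln n)."""
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8 for a stable screening size")
    return int(math.floor(2.0 * n_samples / math.log(n_samples)))


def sis_screen(beta_est: PathEstimates, n_samples: int, d: int | None = None) -> list[str]:
    """Top-d candidate sites by |t| of the mediator→outcome association.

    Ties in |t| are broken by site id so the ordering is deterministic.  If
    fewer than d sites were tested, all are returned (still ordered).
    """
    if d is None:
        d = default_sis_size(n_samples)
    if d < 1:
        raise ValueError("d must be >= 1")
    tab = beta_est.table
    # stable sort on -|t| after an id pre-sort implements the tie rule
    by_id = tab.iloc[tab.index.argsort()]
    order = by_id.iloc[(-by_id["t"].abs().to_numpy()).argsort(kind="stable")]
    return list(order.index[:d])
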