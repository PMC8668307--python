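"""Rework-risk propagation analysis.

Each dependency pair carries a risk factor ``R = P_ir * RI`` combining its
rework probability with the consumer's rework impact.  Treating n-step
propagation along a pair as the power R^n, the maximum cumulative risk is
the geometric series

    CR = sum_{n>=1} R^n = R / (1 - R),

finite only for R < 1.  Column sums f_j aggregate the risk an activity
transfers to others, row sums e_i the risk it receives; their grand total
(equal from either side) summarizes the rework-propagation load of the
whole process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DSM

__all__ = [
    "RiskReport",
    "risk_factor",
    "cumulative_risk",
    "risk_margins",
    "analyze_risk",
]


def risk_factor(p_ir: float, ri: float) -> float:
    """Per-pair risk factor R = P_ir * RI."""
    if not 0.0 <= p_ir <= 1.0:
        raise ValueError(f"rework probability {p_ir} outside [0, 1]")
    if not 0.0 <= ri <= 1.0:
        raise ValueError(f"rework impact {ri} outside [0, 1]")
    return p_ir * ri


def cumulative_risk(r: float) -> float:
    """Maximum cumulative propagation risk CR = sum_{n>=1} r^n = r/(1 - r).

    Returns ``inf`` for r >= 1, where the series diverges (unbounded
    risk); batch analysis flags such pairs rather than failing.
    """
    if r < 0.0:
        raise ValueError(f"risk factor {r} must be >= 0")
    if r >= 1.0:
        return math.inf
    return r / (1.0 - r)


def risk_margins(
    cr: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Margins of a cumulative-risk matrix.

    Returns ``(f, e, tr_total, tr_activity)``: column sums f_j (risk
    transferred to others), row sums e_i (risk received), their common
    grand total, and the per-activity combined load f_j + e_j.  Divergent
    (non-finite) entries must be masked to zero by the caller and
    reported separately.
    """
    cr = np.asarray(cr, dtype=float)
    if cr.ndim != 2 or cr.shape[0] != cr.shape[1]:
        raise ValueError("cumulative-risk matrix must be square")
    if not np.all(np.isfinite(cr)):
        raise ValueError("divergent entries must be excluded before summing")
    f = np.array([math.fsum(cr[:, j]) for j in range(cr.shape[1])])
    e = np.array([math.fsum(cr[i, :]) for i in range(cr.shape[0])])
    tr_total = math.fsum(cr.ravel())
    return f, e, tr_total, f + e


@dataclass(frozen=True)
class RiskReport:
    """Risk-propagation analysis of a DSM.

    ``r`` and ``cr`` are matrices over the activity order (``ids``) with
    rows indexing the consumer and columns the provider: ``cr[i, j]`` is
    the cumulative risk that provider j imposes on consumer i, so the
    column sum ``f[j]`` aggregates what j transfers to others and the
    row sum ``e[i]`` what i receives.  ``cr`` holds ``inf`` where the
    series diverges and those pairs are excluded from all margins and
    listed in ``divergent_pairs`` (as provider, consumer).
    ``tr_total`` is the grand sum of finite cumulative risks (identically
    the sum of ``f`` and of ``e``); ``tr_activity`` gives each activity's
    combined transferred-plus-received load f_j + e_j.
    """

    ids: tuple[str, ...]
    r: np.ndarray
    cr: np.ndarray
    f: np.ndarray
    e: np.ndarray
    tr_total: float
    tr_activity: np.ndarray
    divergent_pairs: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        cr_out = [
            [None if not np.isfinite(v) else v for v in row] for row in self.cr
        ]
        return {
            "ids": list(self.ids),
            "r": self.r.tolist(),
            "cr": cr_out,
            "f": self.f.tolist(),
            "e": self.e.tolist(),
            "tr_total": self.tr_total,
            "tr_activity": self.tr_activity.tolist(),
            "divergent_pairs": [list(p) for p in self.divergent_pairs],
            "n_divergent": len(self.divergent_pairs),
        }


def analyze_risk(dsm: DSM) -> RiskReport:
    """Build the full risk report for a DSM.

    For each dependency provider j -> consumer i,
    R[i, j] = P_ir * RI_i (zero where no dependency exists); CR applies
    the geometric series per pair.  Pairs with R >= 1 — e.g. a loop
    observed to rework with certainty — are flagged divergent and left
    out of the margin sums so the totals stay meaningful.
    """
    n = dsm.n
    r = np.zeros((n, n))
    for edge in dsm.edges:
        i = dsm.index(edge.consumer)
        j = dsm.index(edge.provider)
        r[i, j] = risk_factor(
            edge.rework_probability, dsm.activity(edge.consumer).rework_impact
        )
    cr = np.array([[cumulative_risk(v) for v in row] for row in r])

    divergent = tuple(
        (dsm.ids[j], dsm.ids[i])  # reported as (provider, consumer)
        for i in range(n)
        for j in range(n)
        if not np.isfinite(cr[i, j])
    )
    cr_finite = np.where(np.isfinite(cr), cr, 0.0)
    f, e_, tr_total, tr_act = risk_margins(cr_finite)
    return RiskReport(
        ids=dsm.ids,
        r=r,
        cr=cr,
        f=f,
        e=e_,
        tr_total=tr_total,
        tr_activity=tr_act,
        divergent_pairs=divergent,
    )
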