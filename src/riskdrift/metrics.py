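"""Reclassification and discrimination metrics between risk classifications.

Between two classifications of the same individuals into the ordered tiers
Lower < Average < Higher:

* percent reclassified — off-diagonal mass of the 3x3 cross-table;
* collapsed reclassification — same, after merging Lower and Average
  (Higher vs not-Higher);
* downward-from-high — among individuals Higher at the first time point,
  the share no longer Higher at the second;
* net reclassification index (NRI) — net appropriate movement: cases up
  minus cases down, plus controls down minus controls up.

Discrimination is summarised by the AUC, either empirically (weighted
Mann-Whitney probability that a case outscores a control, ties counted
half) or analytically under the binormal model on log scores:

    AUC = Phi(a / sqrt(1 + b^2)),  a = (mu_D - mu_Dbar)/sigma_D,
                                   b = sigma_Dbar/sigma_D

where D marks cases and Dbar controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReclassificationResult",
    "AucResult",
    "reclassification_metrics",
    "nri",
    "odds_change_summary",
    "analytic_auc",
    "empirical_auc",
]

_LABELS = ("Lower", "Average", "Higher")


@dataclass(frozen=True)
class ReclassificationResult:
    """3x3 movement table plus its scalar summaries.

    ``table[r, c]`` is the (weighted) mass classified in tier ``r`` at the
    first time point and tier ``c`` at the second.
    ``downward_from_high`` is NaN when nobody was Higher at the first time
    point (the proportion is undefined, reported as missing).
    ``nri_value`` is None until case/control weights are supplied.
    """

    table: np.ndarray
    percent_reclassified: float
    collapsed_reclassified: float
    downward_from_high: float
    nri_value: float | None = None

    def to_frame(self, normalize: bool = True) -> pd.DataFrame:
        t = self.table / self.table.sum() if normalize else self.table
        return pd.DataFrame(t, index=list(_LABELS), columns=list(_LABELS))

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "percent_reclassified": self.percent_reclassified,
            "collapsed_reclassified": self.collapsed_reclassified,
            "downward_from_high": (
                None if np.isnan(self.downward_from_high) else self.downward_from_high
            ),
            "nri": self.nri_value,
        }


def _cross_table(cat_t1: np.ndarray, cat_t2: np.ndarray, weights: np.ndarray) -> np.ndarray:
    table = np.zeros((3, 3))
    np.add.at(table, (cat_t1.astype(int), cat_t2.astype(int)), weights)
    return table


def _check_lengths(*vectors) -> tuple[np.ndarray, ...]:
    arrays = [np.asarray(v) for v in vectors]
    lengths = {a.shape[0] for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"input vectors have mismatched lengths: {sorted(lengths)}")
    return tuple(arrays)


def reclassification_metrics(
    cat_t1: np.ndarray,
    cat_t2: np.ndarray,
    weights: np.ndarray | None = None,
) -> ReclassificationResult:
    """Cross-tabulate two tier classifications of the same individuals.

    ``weights`` default to 1 per individual; exact-distribution callers pass
    genotype-class probabilities instead.
    """
    cat_t1, cat_t2 = _check_lengths(cat_t1, cat_t2)
    w = np.ones(len(cat_t1)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(cat_t1):
        raise ValueError("weights length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    table = _cross_table(cat_t1, cat_t2, w)
    total = table.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    off_diag = total - np.trace(table)
    high_t1 = table[2].sum()
    downward = (table[2, 0] + table[2, 1]) / high_t1 if high_t1 > 0 else np.nan
    high_moves = table[2, 0] + table[2, 1] + table[0, 2] + table[1, 2]
    return ReclassificationResult(
        table=table,
        percent_reclassified=float(off_diag / total),
        collapsed_reclassified=float(high_moves / total),
        downward_from_high=float(downward) if not np.isnan(downward) else np.nan,
    )


def nri(
    cat_t1: np.ndarray,
    cat_t2: np.ndarray,
    case_weights: np.ndarray,
    control_weights: np.ndarray,
) -> float:
    """Net reclassification index between two tier classifications.

    NRI = (P(case up) - P(case down)) + (P(control down) - P(control up)),
    where up/down means any move in the order Lower < Average < Higher
    (a two-tier jump counts once). Ranges over [-2, 2].
    """
    cat_t1, cat_t2, cw, ctw = _check_lengths(cat_t1, cat_t2, case_weights, control_weights)
    for name, w in (("case", cw), ("control", ctw)):
        if np.any(w < 0):
            raise ValueError(f"{name} weights must be nonnegative")
        if w.sum() <= 0:
            raise ValueError(f"{name} weights must have positive total mass")
    up = (cat_t2 > cat_t1).astype(float)
    down = (cat_t2 < cat_t1).astype(float)
    p_case_up = float(cw @ up) / float(cw.sum())
    p_case_down = float(cw @ down) / float(cw.sum())
    p_ctrl_up = float(ctw @ up) / float(ctw.sum())
    p_ctrl_down = float(ctw @ down) / float(ctw.sum())
    return (p_case_up - p_case_down) + (p_ctrl_down - p_ctrl_up)


def odds_change_summary(
    o_t1: np.ndarray,
    o_t2: np.ndarray,
    thresholds: tuple[float, float] = (0.2, 0.5),
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Proportions with small and large absolute change in normalised odds.

    Returns ``(P(|dO| <= thresholds[0]), P(|dO| > thresholds[1]))``; the two
    need not sum to 1.
    """
    o_t1, o_t2 = _check_lengths(o_t1, o_t2)
    w = np.ones(len(o_t1)) if weights is None else np.asarray(weights, dtype=float)
    delta = np.abs(np.asarray(o_t2, dtype=float) - np.asarray(o_t1, dtype=float))
    total = w.sum()
    small, large = thresholds
    return (
        float(w[delta <= small].sum() / total),
        float(w[delta > large].sum() / total),
    )


@dataclass(frozen=True)
class AucResult:
    """Binormal AUC with the standardised separation inputs retained."""

    a: float
    b: float
    auc: float
    mu_cases: float
    sigma_cases: float
    mu_controls: float
    sigma_controls: float


def analytic_auc(
    mu_cases: float, sigma_cases: float, mu_controls: float, sigma_controls: float
) -> AucResult:
    """Binormal AUC from log-score moments of cases and controls."""
    if sigma_controls < 0:
        raise ValueError("sigma_controls must be >= 0")
    if sigma_cases <= 0:
        if mu_cases != mu_controls:
            raise ValueError(
                "degenerate case distribution (sigma_cases = 0) with distinct means"
            )
        a = 0.0
        b = 0.0
    else:
        a = (mu_cases - mu_controls) / sigma_cases
        b = sigma_controls / sigma_cases
    auc = float(stats.norm.cdf(a / np.sqrt(1.0 + b**2)))
    return AucResult(
        a=a,
        b=b,
        auc=auc,
        mu_cases=mu_cases,
        sigma_cases=sigma_cases,
        mu_controls=mu_controls,
        sigma_controls=sigma_controls,
    )


def empirical_auc(
    scores: np.ndarray,
    case_weights: np.ndarray,
    control_weights: np.ndarray,
) -> float:
    """Weighted Mann-Whitney AUC: P(case score > control score) + P(tie)/2.

    ``scores`` is one vector scored for everyone; ``case_weights`` and
    ``control_weights`` give each observation's mass in the case and
    control populations (they may overlap, as in the rare-disease cohort
    where every individual is both a control and a fractional case).
    """
    scores, cw, ctw = _check_lengths(scores, case_weights, control_weights)
    cw = cw.astype(float)
    ctw = ctw.astype(float)
    if cw.sum() <= 0 or ctw.sum() <= 0:
        raise ValueError("both groups need positive total weight")
    order = np.argsort(scores, kind="stable")
    s = np.asarray(scores, dtype=float)[order]
    cw = cw[order] / cw.sum()
    ctw = ctw[order] / ctw.sum()
    # collapse ties so each distinct score contributes once
    boundaries = np.flatnonzero(np.diff(s)) + 1
    cw_g = np.add.reduceat(cw, np.r_[0, boundaries])
    ctw_g = np.add.reduceat(ctw, np.r_[0, boundaries])
    ctrl_below = np.concatenate([[0.0], np.cumsum(ctw_g)[:-1]])
    return float(np.sum(cw_g * (ctrl_below + 0.5 * ctw_g)))
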