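"""Trend-consistency marker shortlisting.

Intersects the grade-group and recurrence differential analyses and keeps
proteins that behave like progression markers in both:

C1  significant recurrence difference (Mann-Whitney p < alpha);
C2  concordant direction — the recurrence fold change and the last-vs-first
    grade-group fold change point the same way;
C3  a consistent abundance trend across the ordered grade groups, with a
    multiplicative tolerance for small adjacent-group reversals;
C4  significant grade-group difference, via the omnibus Kruskal-Wallis test
    or via at least ``min_pairwise_significant`` of the pairwise contrasts.

A protein is selected iff it passes all four. Every per-criterion verdict
and the branch that satisfied C4 are recorded so the rule can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionCriteria", "MarkerSelectionReport", "select_markers", "criteria_audit"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Tunable thresholds of the selection rule.

    ``trend_tolerance`` is the multiplicative slack for C3: in the up
    direction each grade-group mean must be at least ``trend_tolerance``
    times the previous one (1.0 demands strict non-decrease; the default
    0.95 tolerates a 5% adjacent dip, mirrored for the down direction).
    """

    alpha: float = 0.05
    min_pairwise_significant: int = 3
    trend_tolerance: float = 0.95
    direction_source: str = "bcr_ratio"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_pairwise_significant not in range(1, 7):
            raise ValueError("min_pairwise_significant must be in 1..6")
        if not 0 < self.trend_tolerance <= 1:
            raise ValueError("trend_tolerance must be in (0,1]")


@dataclass
class MarkerSelectionReport:
    """Per-protein criterion verdicts plus the final shortlist."""

    table: pd.DataFrame
    selected: list = field(default_factory=list)
    n_grade_only: int = 0
    n_bcr_only: int = 0

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _mean_columns(grade_table: pd.DataFrame) -> list:
    cols = [c for c in grade_table.columns if c.startswith("mean_g")]
    if len(cols) < 2:
        raise ValueError("grade table must carry at least two group-mean columns")
    return cols


def _pairwise_columns(grade_table: pd.DataFrame) -> list:
    return [c for c in grade_table.columns if c.startswith("mw_g") and c.endswith("_p")]


def select_markers(
    grade_table: pd.DataFrame,
    bcr_table: pd.DataFrame,
    crit: SelectionCriteria = SelectionCriteria(),
) -> MarkerSelectionReport:
    """Apply the four-criterion rule to the two differential tables.

    Both tables are indexed by protein identifier; only proteins present in
    both (each comparison's own filtered set) are evaluated, and the counts
    dropped on either side are reported. A protein whose direction cannot
    be established (zero, missing or non-finite group mean or ratio) is
    flagged unevaluable and never selected.
    """
    common = grade_table.index.intersection(bcr_table.index)
    report = MarkerSelectionReport(
        table=pd.DataFrame(index=common),
        n_grade_only=len(grade_table.index.difference(bcr_table.index)),
        n_bcr_only=len(bcr_table.index.difference(grade_table.index)),
    )
    gt = grade_table.loc[common]
    bt = bcr_table.loc[common]

    mean_cols = _mean_columns(gt)
    pair_cols = _pairwise_columns(gt)
    means = gt[mean_cols].to_numpy(dtype=float)
    ratio = bt["ratio_bcr"].to_numpy(dtype=float)
    mw_p = bt["mw_bcr_p"].to_numpy(dtype=float)
    kw_p = gt["kw_p"].to_numpy(dtype=float)
    n_pair_sig = (gt[pair_cols].to_numpy(dtype=float) < crit.alpha).sum(axis=1)

    n = len(common)
    c1 = mw_p < crit.alpha
    c2 = np.zeros(n, dtype=bool)
    c3 = np.zeros(n, dtype=bool)
    evaluable = np.ones(n, dtype=bool)
    direction = np.empty(n, dtype=object)

    tol = crit.trend_tolerance
    for i in range(n):
        r = ratio[i]
        first, last = means[i, 0], means[i, -1]
        if not (math.isfinite(r) and r > 0 and np.all(np.isfinite(means[i])) and first > 0 and last > 0):
            evaluable[i] = False
            direction[i] = "unevaluable"
            continue
        up = r > 1.0
        direction[i] = "up" if up else ("down" if r < 1.0 else "flat")
        grade_dir = last / first
        if r == 1.0 or grade_dir == 1.0:
            c2[i] = False
            continue
        c2[i] = (r > 1.0) == (grade_dir > 1.0)
        steps = means[i, 1:] / means[i, :-1]
        c3[i] = bool(np.all(steps >= tol)) if up else bool(np.all(steps <= 1.0 / tol))

    kw_branch = kw_p < crit.alpha
    pw_branch = n_pair_sig >= crit.min_pairwise_significant
    c4 = kw_branch | pw_branch
    branch = np.where(
        kw_branch & pw_branch, "both", np.where(kw_branch, "kw", np.where(pw_branch, "pairwise", "none"))
    )
    selected = c1 & c2 & c3 & c4 & evaluable

    report.table = pd.DataFrame(
        {
            "c1_bcr_significant": c1,
            "c2_direction_consistent": c2,
            "c3_trend_consistent": c3,
            "c4_grade_significant": c4,
            "c4_branch": branch,
            "direction": direction,
            "evaluable": evaluable,
            "n_pairwise_significant": n_pair_sig,
            "selected": selected,
        },
        index=common,
    )
    report.table.index.name = "protein_id"
    report.selected = list(common[selected])
    return report


def criteria_audit(report: MarkerSelectionReport) -> pd.DataFrame:
    """Per-criterion attrition of the shortlist rule.

    ``removed_alone`` counts evaluable proteins failing that criterion
    irrespective of the others; ``removed_cumulative`` counts proteins
    first rejected at that criterion when applied in order C1..C4.
    """
    t = report.table
    crits = [
        "c1_bcr_significant",
        "c2_direction_consistent",
        "c3_trend_consistent",
        "c4_grade_significant",
    ]
    ev = t["evaluable"]
    alive = ev.copy()
    rows = []
    for c in crits:
        fails = ev & ~t[c]
        newly_removed = alive & ~t[c]
        rows.append(
            {
                "criterion": c,
                "removed_alone": int(fails.sum()),
                "removed_cumulative": int(newly_removed.sum()),
                "surviving": int((alive & t[c]).sum()),
            }
        )
        alive = alive & t[c]
    audit = pd.DataFrame(rows)
    audit.attrs["n_unevaluable"] = int((~ev).sum())
    audit.attrs["n_selected"] = int(t["selected"].sum())
    return audit
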