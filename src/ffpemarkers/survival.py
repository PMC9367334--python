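"""Median-cutoff expression dichotomization with Kaplan-Meier / log-rank.

Samples are split at the gene-specific median (strictly above the median is
"high"; ties at the median go to "low"), follow-up beyond a fixed horizon
(default 60 months, i.e. 5-year survival) is administratively censored, and
the two groups are compared with the standard log-rank chi-square test
(1 degree of freedom). Estimation and testing are delegated to lifelines.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from ffpemarkers.stats import TestResult

__all__ = ["median_split", "apply_horizon", "km_curve", "logrank_test", "SurvivalDataset"]

DEFAULT_HORIZON_MONTHS = 60.0


class SurvivalDataset(pd.DataFrame):
    """Per-sample (time, event, expression[, group]) table.

    A thin DataFrame subclass so results keep their provenance; construct
    with columns ``time_months`` (non-negative), ``event`` (0/1 or bool)
    and ``expression``.
    """

    _metadata: list = []

    @property
    def _constructor(self):
        return SurvivalDataset

    @classmethod
    def from_columns(cls, time_months, event, expression) -> "SurvivalDataset":
        df = cls(
            {
                "time_months": np.asarray(time_months, dtype=float),
                "event": np.asarray(event).astype(bool),
                "expression": np.asarray(expression, dtype=float),
            }
        )
        if (df["time_months"] < 0).any():
            raise ValueError("survival times must be non-negative")
        return df


def median_split(expr) -> tuple[np.ndarray, bool]:
    """Dichotomize at the median: ``high`` iff value > median, else ``low``.

    The median is the midpoint-of-middle-order-statistics convention
    (``numpy.median``). Returns (labels, degenerate) where ``degenerate``
    flags an all-identical vector (every sample labelled low).
    """
    v = np.asarray(expr, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 samples")
    med = np.median(v)
    labels = np.where(v > med, "high", "low")
    degenerate = np.unique(v).size == 1
    return labels, degenerate


def apply_horizon(time_months, event, horizon_months: float = DEFAULT_HORIZON_MONTHS):
    """Administratively censor observations beyond the horizon."""
    t = np.asarray(time_months, dtype=float)
    e = np.asarray(event).astype(bool)
    over = t > horizon_months
    return np.where(over, horizon_months, t), np.where(over, False, e)


def km_curve(
    ds: pd.DataFrame,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    group_col: str = "group",
) -> dict[str, pd.DataFrame]:
    """Product-limit survival function per group, censored at the horizon.

    Returns, per group, a DataFrame with columns ``time`` and ``survival``
    (the Kaplan-Meier estimate evaluated at each distinct observed time).
    """
    out = {}
    for grp, sub in ds.groupby(group_col, sort=True):
        t, e = apply_horizon(sub["time_months"], sub["event"], horizon_months)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        sf = kmf.survival_function_
        out[grp] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return out


def logrank_test(
    ds: pd.DataFrame,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    group_col: str = "group",
) -> TestResult:
    """Two-group log-rank chi-square test within the horizon.

    The statistic is the standard observed-minus-expected sum over distinct
    event times, referred to chi-square with 1 df. No events within the
    horizon in either group gives p = 1 with method ``"logrank-degenerate"``.
    """
    groups = sorted(ds[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    a = ds[ds[group_col] == groups[0]]
    b = ds[ds[group_col] == groups[1]]
    ta, ea = apply_horizon(a["time_months"], a["event"], horizon_months)
    tb, eb = apply_horizon(b["time_months"], b["event"], horizon_months)
    n = (len(a), len(b))
    if ea.sum() + eb.sum() == 0:
        return TestResult(0.0, 1.0, "logrank-degenerate", n, False)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if math.isnan(p):
        stat, p = 0.0, 1.0
    return TestResult(stat, p, "logrank", n, False)
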