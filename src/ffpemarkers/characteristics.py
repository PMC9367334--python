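"""Cohort-characteristics statistics.

Exact Fisher test of independence on r x c contingency tables (the
conditional test given both margins, with the two-sided probability-
ordering rule: the p-value sums the multivariate hypergeometric
probabilities of every table, with the observed margins, no more probable
than the observed one). Continuous covariates are compared with the rank
tests from :mod:`ffpemarkers.stats`, and ``characteristics_table``
assembles the per-variable summary a clinical cohort table reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ffpemarkers.stats import TestResult, kruskal_wallis, mann_whitney

__all__ = ["ContingencyTable", "fisher_exact_rc", "characteristics_table"]

#: Relative slack guarding the "no more probable than observed" comparison
#: against floating-point ties between equally likely tables.
PROB_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Non-negative integer counts with optional row/column level labels."""

    counts: np.ndarray
    row_labels: tuple = None
    col_labels: tuple = None

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValueError("contingency table counts must be integers")
            a = np.round(a).astype(np.int64)
        if (a < 0).any():
            raise ValueError("contingency table counts must be non-negative")
        if a.sum() < 1:
            raise ValueError("contingency table total count must be >= 1")
        object.__setattr__(self, "counts", a.astype(np.int64))

    def trimmed(self) -> np.ndarray:
        """Counts with all-zero rows and columns dropped."""
        a = self.counts
        a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
        return a


def _log_table_prob(a: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(a + 1).sum()


def fisher_exact_rc(table, method: str = "exact", n_mc: int = 100_000, rng=None) -> TestResult:
    """Two-sided exact Fisher test of independence on an r x c table.

    The null distribution is multivariate hypergeometric over all tables
    sharing the observed margins; the two-sided p-value sums the
    probabilities of tables whose probability does not exceed the observed
    table's (within relative tolerance ``PROB_REL_TOL``), matching the
    convention of R's ``fisher.test``. Enumeration is exhaustive
    (``method="exact"``, the default); ``method="monte_carlo"`` estimates
    the same quantity from ``n_mc`` Patefield draws of margin-conditioned
    tables.

    Degenerate tables (fewer than two informative rows or columns after
    dropping all-zero ones) return p = 1 with ``method`` suffixed
    ``"-degenerate"``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    a = table.trimmed()
    n_cells = a.size
    if a.shape[0] < 2 or a.shape[1] < 2:
        return TestResult(0.0, 1.0, f"{method}-degenerate", tuple(np.atleast_1d(a.sum(axis=0))), False)

    rows = a.sum(axis=1)
    cols = a.sum(axis=0)
    n = a.sum()
    log_margin_const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = _log_table_prob(a, log_margin_const)
    # probability-ordering cutoff with relative slack on the probability scale
    cutoff = logp_obs + np.log1p(PROB_REL_TOL)

    if method == "monte_carlo":
        rng = np.random.default_rng(rng)
        from scipy.stats import random_table

        draws = random_table(rows, cols).rvs(size=n_mc, method="patefield", random_state=rng)
        logp = log_margin_const - gammaln(np.asarray(draws) + 1).sum(axis=(1, 2))
        p = float(np.mean(logp <= cutoff))
        return TestResult(float(np.exp(logp_obs)), p, "monte_carlo", tuple(cols), False)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    # Exhaustive enumeration of tables with the observed margins.
    # Orientation and row order do not change the p-value, so enumerate over
    # the smaller dimension and leave the heaviest row forced (the last row
    # and the last column of every table are determined by the margins);
    # infeasible branches are pruned via remaining-margin bounds.
    if a.shape[0] > a.shape[1]:
        a = a.T
        rows, cols = cols, rows
    order = np.argsort(rows)
    rows = rows[order]
    r, c = len(rows), len(cols)
    row_list = [int(x) for x in rows]
    col_start = tuple(int(x) for x in cols)
    gl = [float(g) for g in gammaln(np.arange(int(n) + 2))]  # gammaln(k+1) = gl[k+1]
    lmc = float(log_margin_const)
    cut = float(cutoff)
    p_sum = 0.0
    exp = np.exp

    def rec(row_idx: int, col_rem: tuple, acc_log: float):
        nonlocal p_sum
        if row_idx == r - 1:
            # last (heaviest) row forced by column remainders
            logp = lmc + acc_log - sum(gl[x + 1] for x in col_rem)
            if logp <= cut:
                p_sum += exp(logp)
            return
        row_total = row_list[row_idx]

        def fill(col_idx: int, row_rem: int, col_rem_local: tuple, acc: float):
            if col_idx == c - 1:
                x = row_rem
                if x <= col_rem_local[col_idx]:
                    nc = col_rem_local[:col_idx] + (col_rem_local[col_idx] - x,)
                    rec(row_idx + 1, nc, acc - gl[x + 1])
                return
            later_capacity = sum(col_rem_local[col_idx + 1 :])
            lo = max(0, row_rem - later_capacity)
            hi = min(row_rem, col_rem_local[col_idx])
            for x in range(lo, hi + 1):
                nc = (
                    col_rem_local[:col_idx]
                    + (col_rem_local[col_idx] - x,)
                    + col_rem_local[col_idx + 1 :]
                )
                fill(col_idx + 1, row_rem - x, nc, acc - gl[x + 1])

        fill(0, row_total, col_rem, acc_log)

    rec(0, col_start, 0.0)
    return TestResult(float(np.exp(logp_obs)), min(float(p_sum), 1.0), "exact", tuple(cols), False)


def characteristics_table(
    ann: pd.DataFrame,
    grouping: str,
    continuous: list | None = None,
    categorical: list | None = None,
) -> pd.DataFrame:
    """Cohort-characteristics summary stratified by ``grouping``.

    Continuous covariates are summarized as ``mean +/- SD`` per stratum with
    a Kruskal-Wallis p when there are more than two strata or a Mann-Whitney
    p for two; categorical covariates are cross-tabulated (counts per
    stratum) with an exact Fisher r x c p. One p-value per variable; a
    covariate with no observed values yields an NA p. Samples with a
    missing grouping label are excluded.

    Column layout mirrors a clinical baseline-characteristics table: ``variable, level``, one
    column per stratum, ``p_value``.
    """
    if grouping not in ann.columns:
        raise ValueError(f"grouping column {grouping!r} not in annotation")
    ann = ann[ann[grouping].notna()]
    strata = list(pd.unique(ann[grouping]))
    if continuous is None:
        continuous = [
            c
            for c in ann.columns
            if c != grouping and pd.api.types.is_numeric_dtype(ann[c]) and ann[c].nunique() > 6
        ]
    if categorical is None:
        categorical = [
            c
            for c in ann.columns
            if c != grouping and c not in continuous and not pd.api.types.is_numeric_dtype(ann[c])
        ]

    rows = []
    sizes = {s: int((ann[grouping] == s).sum()) for s in strata}
    rows.append({"variable": "n", "level": "", **{s: str(sizes[s]) for s in strata}, "p_value": np.nan})

    for var in continuous:
        groups = [ann.loc[ann[grouping] == s, var].dropna().to_numpy() for s in strata]
        cells = {
            s: f"{g.mean():.1f} ± {g.std(ddof=1):.2f}" if g.size else "NA"
            for s, g in zip(strata, groups)
        }
        nonempty = [g for g in groups if g.size]
        if len(nonempty) < 2:
            p = np.nan
        elif len(strata) == 2:
            p = mann_whitney(nonempty[0], nonempty[1], mode="asymptotic").p_value
        else:
            p = kruskal_wallis(nonempty, mode="asymptotic").p_value
        rows.append({"variable": var, "level": "", **cells, "p_value": p})

    for var in categorical:
        sub = ann[ann[var].notna()]
        if sub.empty:
            rows.append({"variable": var, "level": "", **{s: "NA" for s in strata}, "p_value": np.nan})
            continue
        ct = pd.crosstab(sub[var], sub[grouping]).reindex(columns=strata, fill_value=0)
        p = fisher_exact_rc(ct.to_numpy()).p_value
        for j, level in enumerate(ct.index):
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    **{s: str(int(ct.iloc[j][s])) for s in strata},
                    "p_value": p if j == 0 else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    return out
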