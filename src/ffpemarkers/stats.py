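"""Nonparametric differential-abundance testing.

Mann-Whitney (two-group) and Kruskal-Wallis (k-group) rank tests with
midrank tie handling, each available in an asymptotic mode (normal /
chi-square reference, tie-corrected variance) and an exact mode that
enumerates the permutation null of the rank statistic — feasible for the
small pooled sizes where the asymptotic reference is least trustworthy.
``differential_analysis`` applies them protein-by-protein to a
ppm-normalized matrix and assembles the per-protein result table;
``volcano_table`` derives the log2-ratio / -log10-p export for two-group
comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "kruskal_wallis",
    "differential_analysis",
    "volcano_table",
    "EXACT_N_CAP",
]

#: Largest pooled sample size at which ``mode="auto"`` enumerates exactly.
EXACT_N_CAP = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test.

    ``method`` records whether the p-value came from the asymptotic
    reference distribution or from exact permutation enumeration;
    ``tie_corrected`` flags whether tied observations were present (and
    hence the variance/H tie correction engaged).
    """

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    tie_corrected: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size == 0:
        raise ValueError(f"group {name!r} is empty")
    return a


def _u_statistic(pooled_ranks: np.ndarray, n1: int) -> float:
    """Mann-Whitney U for the first group, from midranks of the pooled data."""
    r1 = pooled_ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y, mode: str = "auto", continuity: bool = False) -> TestResult:
    """Two-sided Mann-Whitney test with midrank tie handling.

    Parameters
    ----------
    x, y
        The two samples (non-empty).
    mode
        ``"asymptotic"``: normal approximation with tie-corrected variance
        (no continuity correction unless ``continuity=True``).
        ``"exact"``: full enumeration of the C(n, n1) group labelings of the
        pooled midranks; the two-sided p is the probability of a U at least
        as far from its null mean n1*n2/2 as observed (the U null
        distribution is symmetric about that mean even under ties).
        ``"auto"``: exact when n1+n2 <= EXACT_N_CAP, else asymptotic.

    Two identical multisets, or all values tied, give p = 1.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = sps.rankdata(pooled)
    tied = np.unique(pooled).size < pooled.size
    u = _u_statistic(ranks, n1)

    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_N_CAP else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")

    if np.unique(pooled).size == 1:
        return TestResult(u, 1.0, mode, (n1, n2), True)

    if mode == "exact":
        mu = n1 * n2 / 2.0
        dev = abs(u - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            up = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(up - mu) >= dev - 1e-12:
                extreme += 1
        return TestResult(u, extreme / total, "exact", (n1, n2), tied)

    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method="asymptotic", use_continuity=continuity
    )
    p = float(res.pvalue)
    if math.isnan(p):  # zero tie-corrected variance
        p = 1.0
    return TestResult(u, p, "asymptotic", (n1, n2), tied)


def _h_statistic(pooled_ranks: np.ndarray, sizes: list[int]) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled midranks."""
    n = pooled_ranks.size
    h = 0.0
    start = 0
    for ni in sizes:
        r = pooled_ranks[start : start + ni].sum()
        h += r * r / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all observations tied
        return 0.0
    return h / denom


def kruskal_wallis(groups, mode: str = "auto") -> TestResult:
    """Tie-corrected Kruskal-Wallis H test over >= 2 groups.

    Asymptotic mode refers H to chi-square with k-1 degrees of freedom;
    exact mode enumerates every assignment of the pooled midranks to groups
    of the observed sizes and reports P(H >= H_obs). All values identical
    gives H = 0, p = 1.
    """
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    tied = np.unique(pooled).size < pooled.size
    n = pooled.size

    if mode == "auto":
        mode = "exact" if n <= EXACT_N_CAP else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")

    if np.unique(pooled).size == 1:
        return TestResult(0.0, 1.0, mode, tuple(sizes), True)

    h_obs = _h_statistic(ranks, sizes)

    if mode == "exact":
        total = 0
        extreme = 0
        for perm_ranks in _group_assignments(ranks, sizes):
            h = _h_statistic(perm_ranks, sizes)
            total += 1
            if h >= h_obs - 1e-12:
                extreme += 1
        return TestResult(h_obs, extreme / total, "exact", tuple(sizes), tied)

    p = float(sps.chi2.sf(h_obs, df=len(sizes) - 1))
    return TestResult(h_obs, p, "asymptotic", tuple(sizes), tied)


def _group_assignments(ranks: np.ndarray, sizes: list[int]):
    """Yield pooled-rank vectors for every split into groups of the given sizes.

    Enumerates index combinations recursively; the yielded vector lists
    group 1's ranks first, then group 2's, etc., matching ``_h_statistic``.
    """
    n = ranks.size

    def rec(remaining: tuple, sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield list(remaining)
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(range(len(remaining)), k):
            chosen_set = set(chosen)
            rest = tuple(remaining[i] for i in range(len(remaining)) if i not in chosen_set)
            head = [remaining[i] for i in chosen]
            for tail in rec(rest, sizes_left[1:]):
                yield head + tail

    for assignment in rec(tuple(range(n)), sizes):
        yield ranks[assignment]


def _sanitize(label) -> str:
    """Column-name token for a group label: '4-5' -> '45', 'BCR+' -> 'bcrpos'."""
    s = str(label)
    s = s.replace("+", "pos").replace("-", "" if any(c.isdigit() for c in s) else "neg")
    return "".join(c for c in s if c.isalnum()).lower()


def differential_analysis(
    m,
    g,
    design: str = "multigroup",
    alpha: float = 0.05,
    mode: str = "asymptotic",
    missing: str = "zero",
) -> pd.DataFrame:
    """Per-protein rank testing of a ppm-normalized, presence-filtered matrix.

    ``design="multigroup"`` (grade groups): Kruskal-Wallis across all strata
    plus every pairwise Mann-Whitney contrast and per-group means.
    ``design="two_group"`` (recurrence status): Mann-Whitney plus group
    means, the mean ratio first-group/second-group, and volcano columns.

    Samples without a group label are excluded. Missing abundances follow
    the ``missing`` convention ('zero' by default) *before* ranking, so
    undetected proteins enter the tests as zeros and create ties the
    midrank machinery absorbs. ``significant`` flags raw p < ``alpha``
    (no multiplicity adjustment; a Benjamini-Hochberg column ``bh_q`` is
    emitted for reference but plays no role in selection).
    """
    if design not in ("multigroup", "two_group"):
        raise ValueError(f"unknown design {design!r}")
    g.validate_against(m)
    labeled = [s for s in m.sample_ids if s in g.mapping]
    vals = m.filled(missing).loc[:, labeled]
    groups = [grp for grp in g.groups if g.samples_in(grp)]
    if design == "two_group" and len(groups) != 2:
        raise ValueError(f"two_group design needs exactly 2 groups, got {len(groups)}")
    cols_per_group = {grp: [s for s in labeled if g.mapping[s] == grp] for grp in groups}

    out = {}
    for grp in groups:
        block = vals[cols_per_group[grp]]
        if missing == "exclude":
            out[f"mean_g{_sanitize(grp)}"] = block.mean(axis=1, skipna=True)
        else:
            out[f"mean_g{_sanitize(grp)}"] = block.mean(axis=1)

    arrays = {grp: vals[cols_per_group[grp]].to_numpy() for grp in groups}

    def row_groups(i):
        per = []
        for grp in groups:
            a = arrays[grp][i]
            per.append(a[~np.isnan(a)] if missing == "exclude" else a)
        return per

    n = m.n_proteins
    if design == "multigroup":
        kw_p = np.empty(n)
        pair_cols = {}
        pairs = [(b, a) for a, b in itertools.combinations(range(len(groups)), 2)]
        for hi, lo in pairs:
            pair_cols[(hi, lo)] = np.empty(n)
        for i in range(n):
            per = row_groups(i)
            kw_p[i] = kruskal_wallis(per, mode=mode).p_value
            for hi, lo in pairs:
                pair_cols[(hi, lo)][i] = mann_whitney(per[hi], per[lo], mode=mode).p_value
        out["kw_p"] = kw_p
        for (hi, lo), col in pair_cols.items():
            out[f"mw_g{_sanitize(groups[hi])}v{_sanitize(groups[lo])}_p"] = col
        table = pd.DataFrame(out, index=m.protein_ids)
        table["significant"] = table["kw_p"] < alpha
        table["bh_q"] = _bh(table["kw_p"].to_numpy())
    else:
        mw_p = np.empty(n)
        for i in range(n):
            a, b = row_groups(i)
            mw_p[i] = mann_whitney(a, b, mode=mode).p_value
        out["mw_bcr_p"] = mw_p
        table = pd.DataFrame(out, index=m.protein_ids)
        num = table[f"mean_g{_sanitize(groups[0])}"]
        den = table[f"mean_g{_sanitize(groups[1])}"]
        with np.errstate(divide="ignore", invalid="ignore"):
            table["ratio_bcr"] = num / den
            table["log2fc"] = np.log2(table["ratio_bcr"])
        table["neglog10p"] = -np.log10(table["mw_bcr_p"].clip(lower=np.nextafter(0, 1)))
        table["significant"] = table["mw_bcr_p"] < alpha
        table["bh_q"] = _bh(mw_p)
    table.index.name = "protein_id"
    return table


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def volcano_table(dt: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Volcano export for a two-group differential table.

    Columns: ``log2fc``, ``neglog10p`` and a significance class —
    ``up-in-group1`` (ratio > 1 and p < alpha), ``up-in-group2``
    (ratio < 1 and p < alpha), ``ns`` otherwise. Proteins whose ratio is
    zero, infinite or undefined (a zero group mean) are excluded and
    counted in the ``n_excluded`` attribute of the result.
    """
    if "ratio_bcr" not in dt.columns:
        raise ValueError("volcano export requires a two-group differential table")
    finite = np.isfinite(dt["log2fc"].to_numpy()) & np.isfinite(dt["neglog10p"].to_numpy())
    v = dt.loc[finite, ["log2fc", "neglog10p", "mw_bcr_p", "ratio_bcr"]].copy()
    cls = np.where(
        (v["mw_bcr_p"] < alpha) & (v["ratio_bcr"] > 1),
        "up-in-group1",
        np.where((v["mw_bcr_p"] < alpha) & (v["ratio_bcr"] < 1), "up-in-group2", "ns"),
    )
    v["class"] = cls
    v = v[["log2fc", "neglog10p", "class"]]
    v.attrs["n_excluded"] = int((~finite).sum())
    return v
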