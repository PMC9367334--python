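"""Rank tests against brute-force permutation oracles, and the differential table."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from ffpemarkers.abundance import GroupAssignment, ppm_normalize, presence_filter
from ffpemarkers.stats import (
    differential_analysis,
    kruskal_wallis,
    mann_whitney,
    volcano_table,
)


def brute_force_mw_p(x, y):
    """Independent enumeration oracle: two-sided tail of U around its mean,
    recomputing U from scratch (pairwise comparisons) for every labeling."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(sample, rest):
        return sum((a > b) + 0.5 * (a == b) for a in sample for b in rest)

    u_obs = u_of(list(x), list(y))
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s = [pooled[i] for i in idx]
        r = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(s, r) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def brute_force_kw_p(groups):
    """Independent enumeration oracle for the k-group rank statistic, using
    scipy's H computation on every regrouping of the pooled data."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]

    def h_of(parts):
        try:
            return sps.kruskal(*parts).statistic
        except ValueError:  # all identical
            return 0.0

    h_obs = h_of(groups)
    total = extreme = 0
    idx_all = range(len(pooled))

    def splits(remaining, szs):
        if len(szs) == 1:
            yield [list(remaining)]
            return
        for chosen in itertools.combinations(range(len(remaining)), szs[0]):
            chosen_set = set(chosen)
            rest = [remaining[i] for i in range(len(remaining)) if i not in chosen_set]
            head = [remaining[i] for i in chosen]
            for tail in splits(rest, szs[1:]):
                yield [head] + tail

    for parts_idx in splits(list(idx_all), sizes):
        parts = [pooled[p] for p in parts_idx]
        total += 1
        if h_of(parts) >= h_obs - 1e-12:
            extreme += 1
    return extreme / total


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        for mode in ("exact", "asymptotic"):
            assert mann_whitney([1, 1, 2], [2, 1, 1], mode=mode).p_value == 1.0

    def test_complete_separation_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of the 20 labelings

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 2, 3], [2, 3, 4, 5]),
            ([0, 0, 0, 1, 5], [0, 2, 2, 6]),
            ([3, 1, 4, 1, 5], [9, 2, 6, 5]),
            ([0, 0, 1], [0, 1, 1, 2]),
        ],
    )
    def test_exact_mode_equals_enumeration_oracle(self, x, y):
        assert mann_whitney(x, y, mode="exact").p_value == pytest.approx(brute_force_mw_p(x, y))

    def test_asymptotic_close_to_exact_with_ties_at_two_by_eight(self):
        x = [0, 0, 1, 2, 2, 3, 5, 5]
        y = [1, 2, 3, 3, 4, 5, 6, 8]
        pa = mann_whitney(x, y, mode="asymptotic").p_value
        pe = mann_whitney(x, y, mode="exact").p_value
        assert pa == pytest.approx(pe, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_auto_switches_on_pooled_size(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6], mode="auto").method == "exact"
        big = list(range(10))
        assert mann_whitney(big, big[::-1] + [3], mode="auto").method == "asymptotic"


class TestKruskalWallis:
    def test_identical_groups_give_h_zero_p_one(self):
        res = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_three_group_h_statistic(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]], mode="asymptotic")
        assert res.statistic == pytest.approx(4.571, abs=5e-4)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1, 2, 0], [0, 0, 4], [5, 1, 2]],
            [[0, 0, 0], [0, 1, 2], [2, 2]],
            [[1, 5], [2, 2, 2], [4, 0, 1]],
        ],
    )
    def test_exact_mode_equals_enumeration_oracle(self, groups):
        assert kruskal_wallis(groups, mode="exact").p_value == pytest.approx(
            brute_force_kw_p(groups)
        )

    def test_heavy_ties_asymptotic_close_to_exact_near_threshold(self):
        # many zeros, as the missing-as-zero convention produces; the
        # chi-square reference tracks the exact permutation p closely in the
        # small-p region where significance calls are made (agreement is
        # looser in the middle of the null distribution)
        groups = [[0, 0, 1, 1], [0, 0, 2, 5], [3, 4, 5, 6]]
        pe = kruskal_wallis(groups, mode="exact").p_value
        pa = kruskal_wallis(groups, mode="asymptotic").p_value
        assert pa == pytest.approx(pe, abs=0.02)

    def test_matches_scipy_h_on_untied_data(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=8), rng.normal(size=10), rng.normal(size=7)]
        mine = kruskal_wallis(groups, mode="asymptotic")
        ref = sps.kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_two_group_case_coincides_with_mann_whitney(self):
        x = [0, 0, 1, 3, 3]
        y = [2, 3, 4, 4]
        assert kruskal_wallis([x, y], mode="exact").p_value == pytest.approx(
            mann_whitney(x, y, mode="exact").p_value
        )
        assert kruskal_wallis([x, y], mode="asymptotic").p_value == pytest.approx(
            mann_whitney(x, y, mode="asymptotic").p_value
        )

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDifferentialAnalysis:
    @pytest.fixture
    def prepared(self, small_cohort):
        ann = small_cohort.annotation
        norm = ppm_normalize(small_cohort.abundance)
        ga = GroupAssignment.from_series(ann["grade_group"].astype(str), order=("1", "2", "3", "4-5"))
        filt, _ = presence_filter(norm, ga)
        return filt, ga, ann

    def test_constant_protein_everything_null(self):
        vals = pd.DataFrame(
            np.full((1, 6), 5.0), index=["P0"], columns=[f"S{i}" for i in range(6)]
        )
        from ffpemarkers.abundance import AbundanceMatrix

        m = AbundanceMatrix(vals, state="ppm")
        g = GroupAssignment({f"S{i}": "a" if i < 3 else "b" for i in range(6)}, order=("a", "b"))
        t = differential_analysis(m, g, design="two_group")
        assert t.loc["P0", "mw_bcr_p"] == 1.0
        assert t.loc["P0", "ratio_bcr"] == pytest.approx(1.0)

    def test_multigroup_matches_per_protein_loop(self, prepared):
        filt, ga, _ = prepared
        table = differential_analysis(filt, ga, design="multigroup")
        vals = filt.filled("zero")
        rng = np.random.default_rng(0)
        for pid in rng.choice(filt.protein_ids, size=12, replace=False):
            groups = [vals.loc[pid, ga.samples_in(g)].to_numpy() for g in ga.groups]
            assert table.loc[pid, "kw_p"] == pytest.approx(
                kruskal_wallis(groups, mode="asymptotic").p_value
            )
            assert table.loc[pid, "mw_g45v1_p"] == pytest.approx(
                mann_whitney(groups[3], groups[0], mode="asymptotic").p_value
            )

    def test_two_group_matches_per_protein_loop(self, small_cohort):
        ann = small_cohort.annotation
        norm = ppm_normalize(small_cohort.abundance)
        gb = GroupAssignment.from_series(
            ann["bcr"].where(ann["bcr"].isin(("BCR+", "BCR-"))), order=("BCR+", "BCR-")
        )
        filt, _ = presence_filter(norm.subset_samples(list(gb.mapping)), gb)
        table = differential_analysis(filt, gb, design="two_group")
        vals = filt.filled("zero")
        for pid in list(filt.protein_ids)[:10]:
            a = vals.loc[pid, gb.samples_in("BCR+")].to_numpy()
            b = vals.loc[pid, gb.samples_in("BCR-")].to_numpy()
            assert table.loc[pid, "mw_bcr_p"] == pytest.approx(
                mann_whitney(a, b, mode="asymptotic").p_value
            )
            if b.mean() > 0:
                assert table.loc[pid, "ratio_bcr"] == pytest.approx(a.mean() / b.mean())

    def test_ratio_inverts_under_group_swap(self, small_cohort):
        ann = small_cohort.annotation
        norm = ppm_normalize(small_cohort.abundance)
        fwd = GroupAssignment.from_series(
            ann["bcr"].where(ann["bcr"].isin(("BCR+", "BCR-"))), order=("BCR+", "BCR-")
        )
        rev = GroupAssignment.from_series(
            ann["bcr"].where(ann["bcr"].isin(("BCR+", "BCR-"))), order=("BCR-", "BCR+")
        )
        filt, _ = presence_filter(norm.subset_samples(list(fwd.mapping)), fwd)
        t1 = differential_analysis(filt, fwd, design="two_group")
        t2 = differential_analysis(filt, rev, design="two_group")
        both_pos = (t1["ratio_bcr"] > 0) & np.isfinite(t1["ratio_bcr"]) & np.isfinite(t2["ratio_bcr"])
        prod = (t1.loc[both_pos, "ratio_bcr"] * t2.loc[both_pos, "ratio_bcr"]).to_numpy()
        np.testing.assert_allclose(prod, 1.0, rtol=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        # no-signal cohort without missingness: p-value CDF near the diagonal
        from ffpemarkers.cohort import CohortSpec, generate_cohort

        ds = generate_cohort(
            CohortSpec(
                n_proteins=800,
                n_planted=0,
                trend_step=1.0,
                bcr_effect=1.0,
                missing_alpha=-50.0,  # detection probability ~1 everywhere
                seed=3,
            )
        )
        norm = ppm_normalize(ds.abundance)
        gb = GroupAssignment.from_series(
            ds.annotation["bcr"].where(ds.annotation["bcr"].isin(("BCR+", "BCR-"))),
            order=("BCR+", "BCR-"),
        )
        filt, _ = presence_filter(norm.subset_samples(list(gb.mapping)), gb)
        t = differential_analysis(filt, gb, design="two_group")
        d = sps.kstest(t["mw_bcr_p"], "uniform").statistic
        assert d < 0.06


class TestVolcano:
    def test_forced_values(self):
        dt = pd.DataFrame(
            {
                "ratio_bcr": [1.0, 2.0, 0.5],
                "mw_bcr_p": [1.0, 0.01, 0.01],
            },
            index=["A", "B", "C"],
        )
        dt["log2fc"] = np.log2(dt["ratio_bcr"])
        dt["neglog10p"] = -np.log10(dt["mw_bcr_p"])
        v = volcano_table(dt)
        assert v.loc["A", ["log2fc", "neglog10p"]].tolist() == [0.0, 0.0]
        assert v.loc["A", "class"] == "ns"
        assert v.loc["B", "log2fc"] == 1.0 and v.loc["B", "class"] == "up-in-group1"
        assert v.loc["C", "class"] == "up-in-group2"

    def test_class_counts_match_reclassification(self, small_cohort):
        ann = small_cohort.annotation
        norm = ppm_normalize(small_cohort.abundance)
        gb = GroupAssignment.from_series(
            ann["bcr"].where(ann["bcr"].isin(("BCR+", "BCR-"))), order=("BCR+", "BCR-")
        )
        filt, _ = presence_filter(norm.subset_samples(list(gb.mapping)), gb)
        t = differential_analysis(filt, gb, design="two_group")
        v = volcano_table(t)
        finite = t.loc[np.isfinite(t["log2fc"])]
        n_up = int(((finite["mw_bcr_p"] < 0.05) & (finite["ratio_bcr"] > 1)).sum())
        n_dn = int(((finite["mw_bcr_p"] < 0.05) & (finite["ratio_bcr"] < 1)).sum())
        counts = v["class"].value_counts()
        assert counts.get("up-in-group1", 0) == n_up
        assert counts.get("up-in-group2", 0) == n_dn
        assert len(v) + v.attrs["n_excluded"] == len(t)
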