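"""ppm normalization, presence filtering, and group means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpemarkers.abundance import (
    AbundanceMatrix,
    DegenerateSampleError,
    GroupAssignment,
    group_means,
    ppm_normalize,
    presence_filter,
)

PPM = 1_000_000.0


def _matrix(arr, proteins=None, samples=None, state="raw"):
    arr = np.asarray(arr, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=proteins, columns=samples), state=state)


class TestPpmNormalize:
    def test_single_protein_column_maps_to_full_scale(self):
        m = _matrix([[500.0]])
        out = ppm_normalize(m)
        assert out.values.iloc[0, 0] == pytest.approx(PPM)
        assert out.state == "ppm"

    def test_forced_arithmetic(self):
        m = _matrix([[2.0], [3.0], [5.0]])
        out = ppm_normalize(m)
        np.testing.assert_allclose(out.values.iloc[:, 0], [200000, 300000, 500000])

    def test_random_matrix_columns_sum_to_scale(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, size=(50, 10))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        out = ppm_normalize(_matrix(vals))
        sums = out.values.fillna(0.0).sum(axis=0)
        np.testing.assert_allclose(sums, PPM, rtol=1e-9)

    def test_missing_entries_stay_missing(self, small_matrix):
        out = ppm_normalize(small_matrix)
        pd.testing.assert_frame_equal(out.values.isna(), small_matrix.values.isna())

    def test_degenerate_sample_named_in_error(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(DegenerateSampleError, match="S1"):
            ppm_normalize(_matrix(vals))

    def test_idempotent_up_to_tolerance(self, small_matrix):
        once = ppm_normalize(small_matrix)
        again = ppm_normalize(AbundanceMatrix(once.values, state="raw"))
        pd.testing.assert_frame_equal(once.values, again.values, rtol=1e-12)

    def test_refuses_already_normalized_state(self, small_matrix):
        out = ppm_normalize(small_matrix)
        with pytest.raises(ValueError, match="already"):
            ppm_normalize(out)


def _grouped_matrix(det_counts, sizes=(22, 27, 23, 14)):
    """One protein detected `det_counts[g]` times in group g, else missing."""
    total = sum(sizes)
    row = np.full(total, np.nan)
    start = 0
    mapping = {}
    for g, (size, k) in enumerate(zip(sizes, det_counts)):
        for j in range(size):
            mapping[f"S{start + j}"] = str(g)
        row[start : start + k] = 10.0
        start += size
    m = _matrix(row[None, :], proteins=["P0"], samples=list(mapping))
    return m, GroupAssignment(mapping)


class TestPresenceFilter:
    def test_fully_detected_protein_kept(self, small_matrix):
        g = GroupAssignment({s: "a" if i < 3 else "b" for i, s in enumerate(small_matrix.sample_ids)})
        filt, report = presence_filter(small_matrix, g, min_frac=0.4)
        assert "P1" in filt.protein_ids  # no missing entries in P1
        assert set(report.columns) == {"protein_id", "group", "n_present", "n_total", "fraction", "kept"}

    def test_threshold_boundary_at_reference_group_sizes(self):
        # 9/22 = 0.409 >= 0.40 in one group is enough; 8/22 = 0.364 is not
        kept, _ = presence_filter(*_grouped_matrix([9, 0, 0, 0]), min_frac=0.40)[0], None
        assert kept.n_proteins == 1
        dropped, _ = presence_filter(*_grouped_matrix([8, 0, 0, 0]), min_frac=0.40)
        assert dropped.n_proteins == 0

    def test_kept_set_matches_brute_force(self, small_cohort):
        m = small_cohort.abundance
        ann = small_cohort.annotation
        g = GroupAssignment.from_series(ann["grade_group"].astype(str))
        filt, report = presence_filter(m, g, min_frac=0.4)
        # independent per-protein loop over raw values
        expected = []
        for pid in m.protein_ids:
            keep = False
            for grp in g.groups:
                cols = g.samples_in(grp)
                vals = m.values.loc[pid, cols]
                frac = ((vals.notna()) & (vals > 0)).sum() / len(cols)
                keep = keep or frac >= 0.4
            if keep:
                expected.append(pid)
        assert list(filt.protein_ids) == expected

    def test_empty_group_is_configuration_error(self, small_matrix):
        g = GroupAssignment(
            {s: "a" if i < 3 else "b" for i, s in enumerate(small_matrix.sample_ids)},
            order=("a", "b", "c"),
        )
        with pytest.raises(ValueError, match="group 'c'"):
            presence_filter(small_matrix, g)

    @given(st.integers(0, 22))
    @settings(max_examples=23, deadline=None)
    def test_monotone_in_min_frac(self, k):
        m, g = _grouped_matrix([k, 0, 0, 0])
        kept_loose = presence_filter(m, g, min_frac=0.3)[0].n_proteins
        kept_tight = presence_filter(m, g, min_frac=0.6)[0].n_proteins
        assert kept_tight <= kept_loose

    def test_commutes_with_normalization(self, small_cohort):
        m = small_cohort.abundance
        g = GroupAssignment.from_series(small_cohort.annotation["grade_group"].astype(str))
        kept_raw = list(presence_filter(m, g)[0].protein_ids)
        kept_ppm = list(presence_filter(ppm_normalize(m), g)[0].protein_ids)
        assert kept_raw == kept_ppm


class TestGroupMeans:
    def test_constant_group(self):
        m = _matrix([[3.0, 3.0, 7.0]], samples=["S0", "S1", "S2"])
        g = GroupAssignment({"S0": "a", "S1": "a", "S2": "b"})
        out = group_means(m, g)
        assert out.loc["P0", "a"] == pytest.approx(3.0)

    def test_missing_as_zero_convention(self):
        m = _matrix([[10.0, np.nan, 20.0]], samples=["S0", "S1", "S2"])
        g = GroupAssignment({"S0": "a", "S1": "a", "S2": "b"})
        out = group_means(m, g, missing="zero")
        assert out.loc["P0", "a"] == pytest.approx(5.0)
        out_ex = group_means(m, g, missing="exclude")
        assert out_ex.loc["P0", "a"] == pytest.approx(10.0)

    def test_matches_manual_group_iteration(self, small_cohort):
        m = ppm_normalize(small_cohort.abundance)
        g = GroupAssignment.from_series(small_cohort.annotation["grade_group"].astype(str))
        out = group_means(m, g)
        for grp in g.groups:
            cols = g.samples_in(grp)
            manual = m.values[cols].fillna(0.0).mean(axis=1)
            np.testing.assert_allclose(out[grp], manual)
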