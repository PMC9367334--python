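"""Shared fixtures: printed reference statistics and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from ffpemarkers.abundance import AbundanceMatrix

# Published per-protein statistics of the seven selected progression/
# recurrence markers (recurrence ratio and p, omnibus grade p, four
# grade-group mean ppm abundances, six pairwise grade contrasts).
SEVEN_MARKERS = ["VCAN", "NPM1", "UQCRH", "SERBP1", "HSPA9", "MRPL3", "HSPE1"]

SEVEN_GRADE = pd.DataFrame(
    {
        "mean_g1": [57.39, 77.31, 5.60, 25.42, 56.82, 11.33, 535.94],
        "mean_g2": [55.18, 78.39, 6.50, 25.11, 63.96, 18.20, 565.24],
        "mean_g3": [193.80, 79.77, 8.98, 34.74, 99.01, 26.33, 705.18],
        "mean_g45": [273.18, 188.05, 33.66, 63.35, 121.72, 56.49, 872.93],
        "kw_p": [5.89e-4, 1.01e-2, 1.16e-2, 1.86e-2, 3.20e-2, 3.28e-2, 6.66e-2],
        "mw_g2v1_p": [9.59e-1, 7.19e-1, 9.17e-1, 8.83e-1, 4.32e-1, 6.23e-1, 6.68e-1],
        "mw_g3v1_p": [2.50e-2, 5.87e-1, 6.85e-1, 5.99e-1, 1.17e-1, 7.67e-1, 8.84e-1],
        "mw_g3v2_p": [1.29e-2, 9.84e-1, 7.81e-1, 6.60e-1, 3.95e-1, 7.62e-1, 7.00e-1],
        "mw_g45v1_p": [1.01e-3, 4.03e-3, 8.07e-3, 7.66e-3, 7.83e-3, 9.73e-3, 1.72e-2],
        "mw_g45v2_p": [5.48e-4, 4.32e-3, 4.90e-3, 4.15e-3, 2.14e-2, 2.29e-2, 1.74e-2],
        "mw_g45v3_p": [2.59e-1, 5.13e-3, 2.39e-2, 3.11e-2, 1.21e-1, 3.26e-2, 3.61e-2],
    },
    index=pd.Index(SEVEN_MARKERS, name="protein_id"),
)

SEVEN_BCR = pd.DataFrame(
    {
        "ratio_bcr": [1.68, 2.00, 4.45, 2.19, 1.80, 2.59, 1.37],
        "mw_bcr_p": [1.83e-2, 1.89e-2, 1.99e-4, 1.27e-2, 1.24e-2, 3.66e-3, 1.19e-2],
    },
    index=pd.Index(SEVEN_MARKERS, name="protein_id"),
)

# Published cohort contingency tables (rows = clinical category levels,
# columns = grade strata or recurrence status) with frozen exact p-values
# independently reproduced with R 4.3 fisher.test during development.
COHORT_TABLES = {
    "stage_by_grade": ([[2, 1, 0, 0], [16, 14, 9, 2], [4, 11, 14, 12], [0, 1, 0, 0]], 0.00141601),
    "nodes_by_grade": ([[22, 27, 22, 12], [0, 0, 1, 2]], 0.0759234),
    "metastasis_by_grade": ([[21, 26, 23, 14], [1, 1, 0, 0]], 0.830096),
    "stage_by_bcr": ([[0, 3], [4, 29], [10, 18], [0, 1]], 0.0963944),
    "nodes_by_bcr": ([[13, 51], [1, 0]], 0.215385),
    "metastasis_by_bcr": ([[13, 50], [1, 1]], 0.387019),
    "grade_by_bcr": ([[4, 17], [3, 19], [4, 10], [3, 5]], 0.447225),
}

# Printed p-values of the same tables, to the precision the source reports.
COHORT_TABLES_PRINTED = {
    "stage_by_grade": 1.40e-3,
    "nodes_by_grade": 7.59e-2,
    "metastasis_by_grade": 8.30e-1,
    "stage_by_bcr": 9.64e-2,
    "nodes_by_bcr": 2.15e-1,
    "metastasis_by_bcr": 3.87e-1,
    "grade_by_bcr": 4.47e-1,
}


@pytest.fixture
def seven_markers():
    return SEVEN_GRADE.copy(), SEVEN_BCR.copy()


@pytest.fixture
def small_matrix():
    """5 proteins x 6 samples with some missing entries, raw state."""
    rng = np.random.default_rng(42)
    vals = rng.lognormal(mean=5, sigma=1, size=(5, 6))
    vals[0, 1] = np.nan
    vals[3, 4] = np.nan
    df = pd.DataFrame(
        vals,
        index=[f"P{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(6)],
    )
    return AbundanceMatrix(values=df, state="raw")


@pytest.fixture
def small_cohort():
    """Fast synthetic cohort used across module tests."""
    from ffpemarkers.cohort import CohortSpec, generate_cohort

    spec = CohortSpec(
        n_per_grade=(8, 8, 8, 8),
        n_bcr_pos=6,
        n_bcr_neg=18,
        bcr_by_grade=((1, 5), (1, 5), (2, 4), (2, 4)),
        n_proteins=120,
        n_planted=12,
        seed=7,
    )
    return generate_cohort(spec)
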