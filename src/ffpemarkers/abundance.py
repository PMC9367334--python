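"""Peak-area matrix containers, ppm normalization, and detection filtering.

Label-free protein abundance is taken as the summed peptide peak area per
protein per sample. A protein that yielded no detected peptides in a sample
is *missing* (NaN), which is distinct from a recorded zero. Each sample is
rescaled to parts-per-million of its total detected signal, and only
proteins detected in at least ``min_frac`` (default 40%) of the samples of
at least one comparison group enter statistical testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PPM_SCALE = 1_000_000.0

__all__ = [
    "AbundanceMatrix",
    "GroupAssignment",
    "DegenerateSampleError",
    "ppm_normalize",
    "presence_filter",
    "group_means",
]


class DegenerateSampleError(ValueError):
    """A sample column has no positive detected value to normalize by."""


@dataclass(frozen=True)
class AbundanceMatrix:
    """Protein x sample abundance matrix with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein identifier with one column per sample.
        ``NaN`` marks a protein not detected in that sample; present values
        must be non-negative reals.
    state
        ``"raw"`` for peak areas as quantified, ``"ppm"`` after per-sample
        rescaling to parts per million.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "ppm"):
            raise ValueError(f"state must be 'raw' or 'ppm', got {self.state!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein identifier: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("present abundance values must be non-negative")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (present, strictly positive) entries.

        An explicitly recorded 0 counts as detected-at-zero for abundance
        arithmetic but not as a detection event for the presence filter.
        """
        return self.values.notna() & (self.values > 0)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        """Restrict to the given samples, preserving state."""
        return replace(self, values=self.values.loc[:, list(sample_ids)])

    def filled(self, missing: str = "zero") -> pd.DataFrame:
        """Return values with the missing-value convention applied.

        ``zero``: absent signal contributes 0 (the default downstream
        convention; no detected peptide means zero summed peak area).
        ``exclude``: leave NaN so statistics drop missing entries.
        """
        if missing == "zero":
            return self.values.fillna(0.0)
        if missing == "exclude":
            return self.values.copy()
        raise ValueError(f"missing convention must be 'zero' or 'exclude', got {missing!r}")


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping from sample identifier to comparison-group label.

    ``order`` fixes the ordinal arrangement of groups (ascending grade
    groups, or the two recurrence strata); it defaults to first-appearance
    order of the mapping values.
    """

    mapping: dict
    order: tuple = field(default=None)

    def __post_init__(self) -> None:
        labels = list(dict.fromkeys(self.mapping.values()))
        if self.order is None:
            object.__setattr__(self, "order", tuple(labels))
        else:
            object.__setattr__(self, "order", tuple(self.order))
            unknown = set(labels) - set(self.order)
            if unknown:
                raise ValueError(f"labels missing from declared order: {sorted(unknown)}")
        if len([g for g in self.order if g in set(labels)]) < 2:
            raise ValueError("need at least 2 non-empty groups")

    @property
    def groups(self) -> tuple:
        return self.order

    def samples_in(self, group) -> list:
        return [s for s, g in self.mapping.items() if g == group]

    def validate_against(self, m: AbundanceMatrix) -> None:
        missing = set(self.mapping) - set(m.sample_ids)
        if missing:
            raise ValueError(f"annotated samples absent from matrix: {sorted(missing)[:5]}")

    @classmethod
    def from_series(cls, s: pd.Series, order=None) -> "GroupAssignment":
        """Build from a sample-indexed label series, dropping NA labels."""
        s = s.dropna()
        return cls(mapping=dict(s), order=order)


def ppm_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale every sample column to parts per million of its total signal.

    Each present value ``v`` in sample ``s`` becomes
    ``v / (sum of present values in s) * 1e6``; missing entries stay missing.

    Raises
    ------
    ValueError
        If the matrix is already ppm-normalized.
    DegenerateSampleError
        If some sample has no present positive value (nothing to scale by).
    """
    if m.state != "raw":
        raise ValueError("matrix is already ppm-normalized")
    totals = m.values.sum(axis=0, skipna=True)
    bad = totals[(totals <= 0) | m.values.notna().sum(axis=0).eq(0)]
    if len(bad) > 0:
        raise DegenerateSampleError(
            f"sample(s) with no positive detected value: {list(bad.index)[:5]}"
        )
    return AbundanceMatrix(values=m.values.div(totals, axis=1) * PPM_SCALE, state="ppm")


def presence_filter(
    m: AbundanceMatrix,
    g: GroupAssignment,
    min_frac: float = 0.40,
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Keep proteins detected in >= ``min_frac`` of samples of some group.

    The rule is evaluated on the *active* samples only (those carrying a
    group label), so re-running a comparison on a sample subset re-derives
    its own analyzable feature set.

    Returns the filtered matrix (all samples retained, rows restricted) and
    a per-protein per-group report with columns
    ``protein_id, group, n_present, n_total, fraction, kept``.
    """
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    g.validate_against(m)
    det = m.detected()
    rows = []
    kept_any = pd.Series(False, index=m.protein_ids)
    for grp in g.groups:
        samples = g.samples_in(grp)
        if not samples:
            raise ValueError(f"group {grp!r} has no samples")
        n_present = det[samples].sum(axis=1)
        frac = n_present / len(samples)
        kept_any |= frac >= min_frac
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": m.protein_ids,
                    "group": grp,
                    "n_present": n_present.to_numpy(),
                    "n_total": len(samples),
                    "fraction": frac.to_numpy(),
                }
            )
        )
    report = pd.concat(rows, ignore_index=True)
    report["kept"] = report["protein_id"].map(kept_any).astype(bool)
    filtered = AbundanceMatrix(values=m.values.loc[kept_any], state=m.state)
    return filtered, report


def group_means(
    m: AbundanceMatrix,
    g: GroupAssignment,
    missing: str = "zero",
) -> pd.DataFrame:
    """Per-protein per-group mean abundance (protein x group DataFrame).

    The missing-value convention is applied before averaging: under
    ``zero`` an undetected protein contributes 0 to the group mean, under
    ``exclude`` it is dropped from the denominator.
    """
    g.validate_against(m)
    vals = m.filled(missing)
    out = {}
    for grp in g.groups:
        samples = g.samples_in(grp)
        if samples:
            out[grp] = vals[samples].mean(axis=1, skipna=True)
    return pd.DataFrame(out)
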