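"""End-to-end orchestration of the marker-discovery pipeline.

normalize -> per-comparison presence filtering -> grade-group differential
(Kruskal-Wallis + pairwise Mann-Whitney) -> recurrence differential
(Mann-Whitney + volcano) -> trend-consistency shortlist -> cohort
characteristics -> optional per-marker survival validation. Every
intermediate table is written as TSV and a manifest records parameters,
seed, software version and the row counts at each stage so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ffpemarkers import __version__
from ffpemarkers import io as fio
from ffpemarkers.abundance import GroupAssignment, ppm_normalize, presence_filter
from ffpemarkers.cohort import GRADE_LABELS, CohortSpec, SyntheticDataset, generate_cohort, read_dataset
from ffpemarkers.characteristics import characteristics_table
from ffpemarkers.shortlist import SelectionCriteria, criteria_audit, select_markers
from ffpemarkers.stats import differential_analysis, volcano_table
from ffpemarkers.survival import DEFAULT_HORIZON_MONTHS, logrank_test, median_split

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

BCR_ORDER = ("BCR+", "BCR-")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-serializable).

    Either ``abundance_path``/``annotation_path`` point at input TSVs or
    ``synthetic=True`` generates a cohort from ``cohort`` (a CohortSpec
    field mapping). Stage toggles and module parameters mirror the
    individual module defaults.
    """

    abundance_path: str | None = None
    annotation_path: str | None = None
    synthetic: bool = False
    cohort: dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    # stage toggles
    run_grade: bool = True
    run_bcr: bool = True
    run_shortlist: bool = True
    run_cohort_table: bool = True
    run_survival: bool = True
    # module parameters
    alpha: float = 0.05
    min_frac: float = 0.40
    missing: str = "zero"
    test_mode: str = "asymptotic"
    trend_tolerance: float = 0.95
    min_pairwise_significant: int = 3
    horizon_months: float = DEFAULT_HORIZON_MONTHS

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", "unknown-key", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.synthetic:
            for p in (self.abundance_path, self.annotation_path):
                if p is None:
                    raise PipelineError("config", "missing-input", "file mode needs both input paths")
                if not Path(p).exists():
                    raise PipelineError("config", "missing-input", f"input not found: {p}")
        if not 0 < self.alpha < 1:
            raise PipelineError("config", "bad-parameter", f"alpha out of range: {self.alpha}")
        if not 0 < self.min_frac <= 1:
            raise PipelineError("config", "bad-parameter", f"min_frac out of range: {self.min_frac}")


def _load(cfg: PipelineConfig) -> SyntheticDataset:
    if cfg.synthetic:
        spec = CohortSpec(**{**cfg.cohort, "seed": cfg.seed})
        return generate_cohort(spec)
    abundance = fio.read_abundance(cfg.abundance_path)
    annotation = fio.read_table(cfg.annotation_path, index_col="sample_id")
    return SyntheticDataset(abundance, annotation, truth=None)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the result bundle.

    The bundle maps stage names to their in-memory tables; everything is
    also written under ``cfg.out_dir`` together with ``manifest.json``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k not in ("cohort",)
        },
        "cohort": dict(cfg.cohort),
        "counts": {},
    }

    ds = _load(cfg)
    ann = ds.annotation
    manifest["counts"]["samples"] = int(ds.abundance.n_samples)
    manifest["counts"]["proteins_identified"] = int(ds.abundance.n_proteins)
    if cfg.synthetic:
        from ffpemarkers.cohort import write_dataset

        write_dataset(ds, out / "dataset")

    try:
        norm = ppm_normalize(ds.abundance)
    except ValueError as e:
        raise PipelineError("normalize", "degenerate-sample", str(e)) from e

    grade_table = bcr_table = None
    if cfg.run_grade:
        ga = GroupAssignment.from_series(ann["grade_group"].astype(str), order=GRADE_LABELS)
        sub = norm.subset_samples(list(ga.mapping))
        filt, report = presence_filter(sub, ga, min_frac=cfg.min_frac)
        fio.write_table(report, out / "filter_report_grade.tsv")
        grade_table = differential_analysis(
            filt, ga, design="multigroup", alpha=cfg.alpha, mode=cfg.test_mode, missing=cfg.missing
        )
        fio.write_table(grade_table, out / "differential_grade.tsv", index_label="protein_id")
        manifest["counts"]["grade_filtered"] = int(len(grade_table))
        manifest["counts"]["grade_significant"] = int(grade_table["significant"].sum())
        bundle["grade"] = grade_table

    if cfg.run_bcr:
        bcr_labels = ann["bcr"].where(ann["bcr"].isin(BCR_ORDER))
        n_unknown = int(bcr_labels.isna().sum())
        ga = GroupAssignment.from_series(bcr_labels, order=BCR_ORDER)
        sub = norm.subset_samples(list(ga.mapping))
        filt, report = presence_filter(sub, ga, min_frac=cfg.min_frac)
        fio.write_table(report, out / "filter_report_bcr.tsv")
        bcr_table = differential_analysis(
            filt, ga, design="two_group", alpha=cfg.alpha, mode=cfg.test_mode, missing=cfg.missing
        )
        fio.write_table(bcr_table, out / "differential_bcr.tsv", index_label="protein_id")
        fio.write_table(volcano_table(bcr_table, alpha=cfg.alpha), out / "volcano_bcr.tsv",
                        index_label="protein_id")
        manifest["counts"]["bcr_excluded_unlabeled"] = n_unknown
        manifest["counts"]["bcr_filtered"] = int(len(bcr_table))
        manifest["counts"]["bcr_significant"] = int(bcr_table["significant"].sum())
        bundle["bcr"] = bcr_table

    if cfg.run_shortlist:
        if grade_table is None or bcr_table is None:
            raise PipelineError("shortlist", "missing-stage", "shortlist needs both differentials")
        crit = SelectionCriteria(
            alpha=cfg.alpha,
            min_pairwise_significant=cfg.min_pairwise_significant,
            trend_tolerance=cfg.trend_tolerance,
        )
        report = select_markers(grade_table, bcr_table, crit)
        fio.write_table(report.table, out / "shortlist_report.tsv", index_label="protein_id")
        (out / "shortlist.txt").write_text("\n".join(map(str, report.selected)) + "\n")
        fio.write_table(criteria_audit(report), out / "shortlist_audit.tsv")
        manifest["counts"]["shortlist_selected"] = report.n_selected
        bundle["shortlist"] = report

    if cfg.run_cohort_table:
        for grouping, name in (("grade_group", "grade"), ("bcr", "bcr")):
            sub_ann = ann.copy()
            if grouping == "bcr":
                sub_ann = sub_ann[sub_ann["bcr"].isin(BCR_ORDER)]
            tab = characteristics_table(
                sub_ann.drop(columns=["surv_months", "event"], errors="ignore"), grouping
            )
            fio.write_table(tab, out / f"characteristics_{name}.tsv")
            bundle[f"characteristics_{name}"] = tab

    if cfg.run_survival and {"surv_months", "event"} <= set(ann.columns) and bundle.get("shortlist"):
        rows = []
        expr = ds.abundance  # raw scale; median split is scale-free per protein
        for pid in bundle["shortlist"].selected:
            vals = expr.values.loc[pid].fillna(0.0).to_numpy()
            labels, degen = median_split(vals)
            sd = pd.DataFrame(
                {
                    "time_months": ann["surv_months"].to_numpy(),
                    "event": ann["event"].astype(bool).to_numpy(),
                    "group": labels,
                }
            )
            res = logrank_test(sd, horizon_months=cfg.horizon_months)
            rows.append(
                {"protein_id": pid, "logrank_stat": res.statistic, "logrank_p": res.p_value,
                 "degenerate": degen}
            )
        surv_table = pd.DataFrame(rows)
        fio.write_table(surv_table, out / "survival_markers.tsv")
        bundle["survival"] = surv_table
        manifest["counts"]["survival_markers_tested"] = len(rows)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
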