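"""Grade-group and recurrence differential testing plus the volcano table."""

import argparse
from pathlib import Path

from ffpemarkers import io as fio
from ffpemarkers.abundance import GroupAssignment, ppm_normalize, presence_filter
from ffpemarkers.cohort import GRADE_LABELS
from ffpemarkers.stats import differential_analysis, volcano_table


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()
    out = Path(args.outdir)

    raw = fio.read_abundance(out / "dataset" / "abundance.tsv")
    ann = fio.read_table(out / "dataset" / "samples.tsv", index_col="sample_id")
    norm = ppm_normalize(raw)

    ga = GroupAssignment.from_series(ann["grade_group"].astype(str), order=GRADE_LABELS)
    filt, _ = presence_filter(norm.subset_samples(list(ga.mapping)), ga)
    grade = differential_analysis(filt, ga, design="multigroup", alpha=args.alpha)
    fio.write_table(grade, out / "differential_grade.tsv", index_label="protein_id")
    print(f"grade groups: {len(grade)} tested, "
          f"{int(grade['significant'].sum())} with omnibus p < {args.alpha}")

    gb = GroupAssignment.from_series(
        ann["bcr"].where(ann["bcr"].isin(("BCR+", "BCR-"))), order=("BCR+", "BCR-")
    )
    filt_b, _ = presence_filter(norm.subset_samples(list(gb.mapping)), gb)
    bcr = differential_analysis(filt_b, gb, design="two_group", alpha=args.alpha)
    fio.write_table(bcr, out / "differential_bcr.tsv", index_label="protein_id")
    fio.write_table(volcano_table(bcr, alpha=args.alpha), out / "volcano_bcr.tsv",
                    index_label="protein_id")
    print(f"recurrence: {len(bcr)} tested, "
          f"{int(bcr['significant'].sum())} with p < {args.alpha}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
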