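"""Apply the trend-consistency selection rule to the two differential tables."""

import argparse
from pathlib import Path

from ffpemarkers import io as fio
from ffpemarkers.shortlist import SelectionCriteria, criteria_audit, select_markers


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results")
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--trend-tolerance", type=float, default=0.95)
    args = parser.parse_args()
    out = Path(args.outdir)

    grade = fio.read_table(out / "differential_grade.tsv", index_col="protein_id")
    bcr = fio.read_table(out / "differential_bcr.tsv", index_col="protein_id")
    crit = SelectionCriteria(alpha=args.alpha, trend_tolerance=args.trend_tolerance)
    rep = select_markers(grade, bcr, crit)

    fio.write_table(rep.table, out / "shortlist_report.tsv", index_label="protein_id")
    (out / "shortlist.txt").write_text("\n".join(map(str, rep.selected)) + "\n")
    audit = criteria_audit(rep)
    fio.write_table(audit, out / "shortlist_audit.tsv")

    print(f"{rep.n_selected} markers selected from {len(rep.table)} evaluated proteins")
    print(audit.to_string(index=False))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
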