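"""Generate the default synthetic cohort and write it under results/dataset."""

import argparse

from ffpemarkers.cohort import CohortSpec, generate_cohort, write_dataset


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="results")
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    spec = CohortSpec(seed=args.seed)
    ds = generate_cohort(spec)
    paths = write_dataset(ds, f"{args.outdir}/dataset")
    n_missing = int(ds.abundance.values.isna().sum().sum())
    total = ds.abundance.values.size
    print(f"cohort: {ds.abundance.n_proteins} proteins x {ds.abundance.n_samples} samples")
    print(f"missing entries: {n_missing}/{total} ({n_missing / total:.1%})")
    for k, v in paths.items():
        print(f"{k}\t{v}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
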