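# ffpemarkers

A tested, reusable implementation of a label-free FFPE proteomics
marker-discovery pipeline for prostate cancer: parts-per-million (ppm)
normalization of protein peak areas, a 40% detection-presence filter,
nonparametric differential testing (Kruskal–Wallis across grade groups,
Mann–Whitney for biochemical-recurrence status and pairwise grade
contrasts), a trend-consistency rule that shortlists candidate markers,
exact Fisher r×c cohort statistics, and median-cutoff Kaplan–Meier /
log-rank survival validation over a 5-year horizon.

Because the original mass-spectrometry deposition is not required, the
package ships a seeded synthetic-cohort generator that reproduces the
statistical structure the analysis assumes — four grade strata of sizes
22/27/23/14, a 14 vs 51 recurrence split, ~1,262 log-normal protein
abundances with intensity-dependent (MNAR) missingness, 50 planted
markers with monotone grade trends and recurrence shifts, and
right-censored survival outcomes linked to the planted signal — so every
stage is testable end to end without external data.

## The science in brief

Archival formalin-fixed paraffin-embedded (FFPE) prostatectomy tissue
can be profiled by label-free LC-MS/MS; each protein's abundance is the
sum of its peptide peak areas. Samples are made comparable by rescaling
each column to parts-per-million of its total signal (column sum =
10⁶). A protein enters testing only if detected in at least 40% of the
samples of at least one comparison group, re-evaluated per comparison
on that comparison's sample subset. Missing entries are treated as zero
abundance inside the rank tests (a documented convention, switchable to
exclusion), which creates heavy ties handled by midranks and
tie-corrected variances.

A candidate progression/recurrence marker must then satisfy four
criteria simultaneously:

1. **C1** — significant between recurrence groups (Mann–Whitney p < 0.05);
2. **C2** — the recurrence direction agrees with the grade-trend
   direction (sign of log recurrence ratio = sign of log grade-4–5/grade-1
   ratio);
3. **C3** — group means change consistently across adjacent grade
   groups, with a 0.95 multiplicative tolerance for near-flat steps;
4. **C4** — significant across grade groups, either by the omnibus
   Kruskal–Wallis test or by at least 3 of the 6 pairwise Mann–Whitney
   contrasts (both branches recorded).

Shortlisted markers are validated by splitting samples at the marker's
median expression and comparing 5-year survival between the high and
low groups with a log-rank test.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic cohort (each is a thin driver over the `ffpemarkers`
library; all write under `results/`):

```bash
python analysis/01_simulate.py --seed 0
python analysis/02_normalize_filter.py
python analysis/03_differential.py
python analysis/04_shortlist.py
python analysis/05_cohort_table.py
python analysis/06_survival.py
```

Actual output of that sequence (seed 0):

```
cohort: 1262 proteins x 86 samples
missing entries: 16075/108532 (14.8%)
...
grade comparison: 1247/1262 proteins pass the 40% filter
recurrence comparison: 1236/1262 proteins pass
grade groups: 1247 tested, 128 with omnibus p < 0.05
recurrence: 1236 tested, 100 with p < 0.05
40 markers selected from 1236 evaluated proteins
              criterion  removed_alone  removed_cumulative  surviving
     c1_bcr_significant           1136                1136        100
c2_direction_consistent            531                  26         74
    c3_trend_consistent           1009                  22         52
   c4_grade_significant           1108                  12         40
...
34/40 markers with log-rank p < 0.05 at the 60-month horizon
```

Comparing `results/shortlist.txt` with `results/dataset/truth.tsv`
shows that all 40 selected proteins at seed 0 are planted markers
(40/50 recovered, sensitivity 0.80, zero false selections).

The same flow is available as a single command:

```bash
ffpemarkers run-all --synthetic --outdir results --seed 0
```

or from a YAML config (`ffpemarkers run-all --config run.yaml`), and
individual stages are exposed as `simulate`, `normalize`, `diff`,
`shortlist`, `cohort`, and `survival` subcommands. File-mode runs
accept any abundance TSV (first column `protein_id`, empty field =
not detected) plus a sample-annotation TSV.

## Library use

```python
from ffpemarkers import (
    CohortSpec, generate_cohort, ppm_normalize, presence_filter,
    GroupAssignment, differential_analysis, select_markers,
)

ds = generate_cohort(CohortSpec(seed=0))
norm = ppm_normalize(ds.abundance)
grades = GroupAssignment.from_series(
    ds.annotation["grade_group"].astype(str), order=("1", "2", "3", "4-5"))
filtered, report = presence_filter(norm, grades)
table = differential_analysis(filtered, grades, design="multigroup")
```

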