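# pvsignals

Disproportionality signal mining for spontaneous adverse-event reports, in the
style of post-marketing pharmacovigilance studies built on the FDA Adverse
Event Reporting System (FAERS) and the Japanese Adverse Drug Event Report
database (JADER).

The package is for pharmacoepidemiologists and methods researchers who want a
tested, reproducible implementation of the standard signal-detection pipeline:
read quarterly report tables, deduplicate cases, select reports naming a focal
suspect drug, build 2×2 report-count tables per adverse-event term, compute
four disproportionality statistics, apply a conjunctive signal rule, and
profile the case series (demographics, annual counts, organ-class
distribution, time to onset, tumor vs non-tumor indication strata).  A
synthetic-report generator with exact ground truth makes every stage testable
with no database download.

## The statistics

For each (drug, event) pair a four-cell report-count table is built:

|                | target event | other events |
|----------------|--------------|--------------|
| focal drug     | a            | b            |
| all other drugs| c            | d            |

with n = a + b + c + d, and the package computes:

- **ROR** (reporting odds ratio): `ROR = ad / bc`, 95% CI
  `exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.
- **PRR** (proportional reporting ratio): `PRR = [a/(a+b)] / [c/(c+d)]` with
  the Yates-corrected chi-squared
  `χ² = n(|ad − bc| − n/2)² / [(a+b)(c+d)(a+c)(b+d)]`.
- **IC** (BCPNN information component): the closed-form posterior mean and
  standard deviation of `log₂ p(x,y)/(p(x)p(y))` under Beta/Dirichlet
  pseudo-count priors; the signal bound is IC − 2SD.
- **EBGM** (empirical-Bayes geometric mean, DuMouchel's gamma–Poisson
  shrinker): `a ~ Poisson(λE)` with `E = (a+b)(a+c)/n`, a two-component gamma
  mixture prior on λ fitted by maximum marginal likelihood over all pairs;
  EBGM is the posterior geometric mean `2^E[log₂ λ]` and EBGM05 the posterior
  5th percentile.

A pair is flagged as a **signal** when all of: a ≥ 3, ROR CI lower bound > 1,
PRR > 2, IC > 0, IC − 2SD > 0, EBGM05 > 2 (each threshold configurable).

## Worked example

Generate a synthetic reporting universe (8,000 background reports, 600 reports
with obinutuzumab as primary suspect, five event terms injected at elevated
relative reporting rates, 3% duplicate case versions), then run the full
pipeline:

```bash
pvsignals simulate --out demo_universe --seed 7 --n-background 8000 --n-drug 600
pvsignals signals --input-dir demo_universe --out demo_out
```

The second command prints the per-stage counters:

```json
{
  "reports_read": 8858,
  "rows_skipped": 0,
  "reports_deduplicated": 8600,
  "focal_reports": 600,
  "pt_pairs": 100,
  "soc_pairs": 11,
  "flagged_pt_pairs": 5,
  "ranked_signals": 5
}
```

8,858 report rows collapse to 8,600 unique cases (the 258 duplicate case
versions are dropped, keeping the latest version of each case), 600 of which
name the focal drug as primary suspect.  All five injected terms — and nothing
else — survive the conjunctive rule.  `demo_out/signals_ranked.csv` holds the
ranked signal table:

```
                    event   a   ror  ror_ci95_low   prr    chi2   ic  ic_minus_2sd  ebgm  ebgm05
    Tumour lysis syndrome 267 17.87         14.95 15.07 1783.15 2.97          2.74  7.90    7.15
         Myelosuppression 156 11.73          9.49 10.69  807.13 2.68          2.40  6.58    5.78
Infusion related reaction 193 11.71          9.67 10.43  984.16 2.67          2.42  6.51    5.79
Cytomegalovirus infection  80  4.72          3.65  4.53  168.70 1.84          1.48  3.85    3.23
              Neutropenia  78  4.56          3.52  4.39  157.26 1.81          1.44  3.77    3.15
```

Reading the first row: 267 deduplicated focal-drug reports mention tumour
lysis syndrome; the odds of that event among focal-drug reports are ~18 times
those in the rest of the corpus (CI well above 1); the empirical-Bayes
shrunken observed-to-expected ratio is 7.9 with a lower bound of 7.2 — far
over every threshold.  The EBGM values sit well below the raw RORs, which is
the shrinkage doing its job.

The same analysis is available as library calls (`generate_reports`,
`deduplicate`, `build_tables`, `score_tables`, `rank_signals`,
`demographic_summary`, `time_to_onset`, `stratified_signals`, ...) — see
`docs/methods.md` for the model details and design choices.

## Data notes

MedDRA is licensed content; the bundled PT→SOC dictionary
(`src/pvsignals/data/pt_soc_synthetic.tsv`) is a synthetic stand-in with the
same two-column structure as a real export and can be swapped via
`--dictionary`.  The drug-synonym lexicon is likewise a table-driven synthetic
stand-in for NLP-based name standardization, swappable via `--lexicon`.
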