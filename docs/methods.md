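# Methods

This note records the models, conventions and design choices behind
`pvsignals`, in enough detail that a maintainer can judge what a passing test
does and does not establish.

## Counting conventions

The counting unit throughout is the **report** (case), never the drug–event
row: a report that lists the same PT twice contributes one count, and a report
with two PTs of one SOC contributes one count to that SOC.  Reports are
deduplicated before any counting, keeping — per (source, case id) — the
highest case version, then the latest receipt date, then the largest report
id.  FAERS and JADER corpora are analyzed separately; no cross-source pooling
is offered, since the two systems have different reporter populations and
coverage.

Contingency margins are **pair-based** by default: for each event,
`a + b` is the number of distinct (focal report, event) pairs, so
`n = a + b + c + d` equals the corpus-wide total of distinct report–event
pairs and is identical across all events at a level.  A report-based
convention (`a + b` = number of focal reports) is available via
`margins="reports"`; the two agree on `a` and `c` and differ only in the
normalizing margins.  Which convention published studies use is rarely
stated; pair-based is the common default in disproportionality software.

Focal ("suspected drug") membership defaults to primary-suspect role only,
with a switch to include secondary suspects — the narrower reading, exposed
because sources rarely say which was used.

## The four statistics

* **ROR** `= ad/bc` with log-scale Wald 95% CI using z = 1.96.  Any zero cell
  makes ROR and PRR not-evaluable by default; the Haldane–Anscombe +0.5
  correction is opt-in (`continuity_correction=True`).  A not-evaluable
  statistic vetoes the signal flag rather than being imputed.
* **PRR** `= [a/(a+b)]/[c/(c+d)]`; its chi-squared uses the Yates-corrected
  form (with the |ad−bc| − n/2 difference floored at zero).  Published tables
  usually do not say whether the correction was applied; the uncorrected form
  is available via `yates=False`.
* **BCPNN IC** uses the closed-form posterior moments of
  `log₂ p(x,y)/(p(x)p(y))` in the pseudo-count parameterization with defaults
  α = β = 2, α₁ = β₁ = γ₁₁ = 1 (all configurable).  Closed-form moments were
  chosen over Monte-Carlo posterior sampling because they are deterministic
  and testable to 1e-9 against a direct evaluation; the "IC025"-style lower
  bound is computed as IC − 2SD, not as a separate 2.5th-percentile
  computation.
* **MGPS/EBGM.**  Counts follow `a ~ Poisson(λE)` with baseline expectation
  `E = (a+b)(a+c)/n`; the prior on λ is
  `p·Gamma(α₁, β₁) + (1−p)·Gamma(α₂, β₂)`.  The marginal over pairs is a
  two-component negative-binomial mixture whose log likelihood is maximized
  with positivity enforced by log-reparameterization (and the weight by a
  logit), parameters capped at e±12, from the documented start
  (0.2, 0.1, 2.0, 4.0, 1/3) plus two fixed alternative starts to guard
  against local optima (L-BFGS-B, then a Nelder–Mead polish).
  Non-convergence is flagged on the result; scoring then suppresses EBGM
  (vetoing every signal flag) unless forced.  The posterior per pair is the
  gamma mixture `Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E)`; EBGM is
  `exp(Q(ψ(α₁+a) − ln(β₁+E)) + (1−Q)(ψ(α₂+a) − ln(β₂+E)))` and EBGM05 solves
  mixture-CDF = 0.05 by Brent root finding between the component quantiles
  (tolerance 1e-8 on λ; the bracket endpoints are returned directly when the
  mixture weight degenerates numerically).

**Zero-count pairs and truncation.**  Corpus fits drop pairs with a = 0 (an
event seen only outside the focal cohort) and correspondingly condition the
likelihood on a ≥ 1, so the exclusion does not bias the fit.  One consequence
worth knowing: under that conditional likelihood the prior *mixture mean* is
not identifiable — the mixture can park arbitrary weight on a near-zero
component that cancels out of the conditional.  This does not affect EBGM
scoring of observed pairs (such a component gets essentially zero posterior
weight at a ≥ 1), but any calibration statement about the fitted prior mean
must be made on a complete pair set fitted with zeros included
(`exclude_zero_counts=False`), which is what the calibration tests and the
acceptance script do.

**Signal rule.**  The default flag is the conjunction a ≥ 3, ROR CI lower
bound > 1, PRR > 2, IC > 0, IC − 2SD > 0, EBGM05 > 2.  A conjunction is the
literal reading of the usual published criteria list; each threshold is
configurable, so any-method variants can be assembled by relaxing the others.

**Ranking.**  Top-N lists sort descending by ROR or by report count, with the
other key as tie-break, after dropping pairs under 3 reports, events equal to
a treated indication, and events containing a disease-progression term
(default list: disease progression, malignant/neoplasm progression, disease
recurrence) — events that reflect the treated disease rather than the drug.

## Synthetic universes and what they show

The generator emulates the structure the analysis assumes:

* a PT catalogue with baseline reporting probabilities (default: 100 terms
  from the bundled dictionary, uniform 0.01);
* per report, `K = max(1, Poisson(mean_pts_per_report))` PT slots filled by
  weighted draws *with replacement*, keeping the distinct set.  This was
  chosen over weighted sampling without replacement because it admits an
  exact per-report inclusion probability `q_j = E_K[1 − (1 − w_j)^K]`, which
  is what the ground-truth expected 2×2 cells use.  The cost is that the
  distinct-PT count per report runs a few percent below the slot mean
  (mean_pts_per_report defaults to 3, matching multi-reaction reports);
* signal injection multiplies chosen PTs' weights by a relative rate and
  renormalizes the whole vector, keeping the PT-count distribution fixed.
  Note the renormalization dilutes the realized odds ratio below the nominal
  relative rate when much weight is injected (20 PTs at rate 10 over baseline
  0.01 yield realized RORs near 3.5, still far above every threshold);
* demographics, countries, reporters, outcomes and indications are drawn from
  configurable categorical mixes whose defaults mirror a large oncology
  case series (male ≈ 50%, >65 ≈ 40%, follicular lymphoma and chronic
  lymphocytic leukaemia dominating the indications);
* receipt dates are uniform over 2013–2025; time to onset is
  Weibull(shape 1.2, scale 20 days) rounded to whole days, whose distribution
  median 20·(ln 2)^(1/1.2) ≈ 14.7 days reproduces the ~two-week onset profile
  typical of infusion-related case series; event date = therapy start + onset
  delay; a configurable fraction of reports lose the start or event date;
* duplicates are exact copies with case version +1 and a receipt date pushed
  7–60 days later, making "keep the latest version" the unique correct
  deduplication.

What passing tests on these universes do **not** show: real reports have
correlated reactions, drug co-medication structure, secular reporting trends,
free-text noise, and duplicates that are *not* exact copies.  Recovery and
calibration results here validate the machinery, not real-world operating
characteristics.

## Descriptive surfaces

Percentages in the demographic table are always recomputed from counts
(half-up rounding to 2 decimals) and audited for self-consistency before a
summary is returned — published tables sometimes carry internally inconsistent
printed percentages, and this package never reproduces a percentage it cannot
derive.  Age groups are <18, 18–65 inclusive, >65; decade age bands map to
their midpoint (so a "60s" band lands at 65 and groups as 18–65).  All age
codes are converted to years (decades ×10, months /12, …).

Time-to-onset uses only reports with day-precision therapy-start and onset
dates and a non-negative delay; bins default to 0–7 / 8–30 / 31–60 / 61–90 /
91–180 / >180 days, edges chosen to support "within 7 days" / "within 30
days" statements and configurable.

Indication stratification classifies a report tumor / non-tumor / unknown by
folded keyword containment over its indications (tumor keywords: lymphoma,
leukaemia/leukemia, macroglobulinaemia, neoplasm; non-tumor: nephritis,
nephrotic, lupus, glomerulonephritis; tumor takes precedence when both match,
since a malignancy indication dominates clinically).  The stratified pipeline
restricts only the focal cohort by default, keeping the full background as
comparator; restricting the background too is a switch.

## Problem sizes

The default test suite runs universes up to 100,000 background + 2,000 focal
reports over 5 seeds for signal recovery, a 5,000-pair MGPS fit-quality check,
and 1,000-table statistic-oracle sweeps; the whole suite completes in a few
minutes on one CPU, and `scripts/acceptance.py` in about ninety seconds.
These sizes give binomial standard errors small enough for the 3–4 SD
calibration bands while staying desk-scale.

## Known limitations

* No stratified (age/sex-adjusted) expected counts; statistics are crude, and
  no multiple-comparison adjustment is applied.
* The FAERS reader targets the modern quarterly ASCII layout only; historical
  schema revisions and NDC/ATC coding are out of scope.
* The JADER dialect here is an ASCII-structured stand-in: real JADER files
  are Japanese-language CSVs whose column semantics this package mirrors but
  whose exact headers it does not reproduce.
* Signal statistics quantify reporting disproportionality, not causality or
  incidence; the package computes, it does not interpret.
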