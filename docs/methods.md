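# Methods

## Scope and data model

`fibrovig` analyses spontaneous adverse-event reports for pulmonary
fibrosis (the two MedDRA preferred terms "Pulmonary fibrosis" and
"Idiopathic pulmonary fibrosis") among 36 DMARDs in seven classes. A
report is a `SafetyReport`: case id, version, event date, age, sex,
country, reporter type, drug mentions (each with role and therapy start),
event PTs and indication PTs. Aggregated sources contribute only
(drug, event count, total count) triples.

Exposure to a drug always means *primary suspect*. Reports suspected of
two distinct DMARDs count once per drug (per-drug 2×2 tables are
independent of one another) and once per class in class-level tables.

## Pre-processing

* **Version retention.** Per case id, the report with the highest version
  number (receipt sequence) is kept. Ties with differing content keep the
  first seen and log a conflict.
* **Key-variable dedup.** Reports sharing (age, sex, country, drug-name
  set, event set, event date) collapse to one; absent values match absent
  values — a deliberately conservative rule, since two all-unknown
  reports cannot be distinguished. The first encountered is kept; the
  published procedure does not state a tie-break.
* **Exclusions.** Reports listing bleomycin (a known fibrogenic agent) or
  the antifibrotics nintedanib/pirfenidone in any role are removed. The
  filter is symmetric over cases and comparators: an asymmetric filter
  would inflate every ROR mechanically.
* **Ages** accept year/month/week/day/decade/hour unit codes; converted
  values outside (0, 120] become absent. **Dates** are kept as
  `YYYYMMDD`/`YYYYMM`/`YYYY` strings: partial dates participate in dedup
  but never in time-to-onset, which needs day resolution.

## Comparator designs

*Full database-wide*: each drug's comparator is every other report in the
database. *Active-comparator restricted*: the population is first cut to
reports with a DMARD as primary suspect and/or ≥1 autoimmune-disorder
indication PT, so cases and comparators share the indication and
confounding by indication is reduced. PF case counts per drug (cell A)
are identical under both designs; only B/C/D change.

The packaged autoimmune PT list is a **synthetic stand-in** (MedDRA is
licensed and cannot be redistributed); production analyses should supply
the licensed list via `TermLists.default(autoimmune_path=...)`.

## Disproportionality

With cells A, B, C, D and N = A+B+C+D:

* ROR = A·D/(B·C); 95% CI by the Woolf log-normal approximation,
  exp(ln ROR ± 1.96·√(1/A+1/B+1/C+1/D)). Any zero cell leaves the ROR
  undefined (reported NA); a Haldane–Anscombe `continuity=0.5` option
  exists for sensitivity analyses but is off by default.
* E = (A+B)(A+C)/N; IC = log₂(A/E), by default shrunken to
  log₂((A+½)/(E+½)), which is finite at A = 0 and monotone in A. IC025 is
  the 2.5th percentile of log₂ X with X ~ Gamma(shape A+½, rate E+½) —
  the posterior of the observed/expected Poisson rate ratio under the
  ½-count prior. The closed-form Gamma quantile is the default; a
  Monte-Carlo posterior (`ic025_method="mc"`) is the config-switchable
  alternative and agrees with it to ~0.01 bits. No authoritative interval
  formula exists for the published IC025 values; this choice reproduces
  them to about ±0.03 bits on reconstructed aggregated tables.
* Signal verdict: A ≥ 3 **and** ROR CI low > 1 **and** IC025 > 0.

Aggregated sources print per-drug event counts and RORs but not per-drug
totals; totals are recovered by inverting the ROR formula,
C = A·(N−A−B)/(A + ROR·B), which is exact up to the printed rounding of
the ROR.

## Risk-factor regression

Case–non-case logistic regression within one class's primary-suspect
reports: outcome = PF report, exposures age group (≤45 reference, 45–65,
>65) or sex (female reference). Adjusted fits add reporting year in
5-year bins, region (continent roll-up of country), and sex (age
analysis) / age group (sex analysis). Estimation is IRLS maximum
likelihood (statsmodels GLM, binomial family; tol 1e-8, max 50
iterations); intervals are Wald, exp(β ± 1.96·se) — profile likelihood is
out of scope. Complete-case is the default; hot-deck or round-robin
random-forest imputation (with per-field imputed flags) is opt-in.

Numerical safeguards: rank deficiency is fatal and names a column;
|β| > 15 or non-convergence flags (quasi-)separation and the stratum is
reported non-estimable rather than with an absurd interval; adjustment
levels rarer than 30 rows are merged into the reference level, since a
near-empty year or region stratum can otherwise be perfectly predicted
and poison the whole fit.

## Time-to-onset

Delay = event date − therapy start of the class's primary-suspect drug,
in days; non-positive or unresolvable delays are dropped and counted.
Trimming removes values outside the 2.5th–97.5th percentiles
(linear-interpolation convention, config-exposed), applied per class:
percentile outliers are class-scale phenomena. A trimmed sample carries a
flag and re-trimming is the identity — literal re-application would shave
a new band off every time, which is never the analyst's intent.
Kruskal–Wallis (midranks, standard tie correction; scipy) compares the
class distributions; Dunn's z with variance
N(N+1)/12 − Σ(t³−t)/(12(N−1)) and Bonferroni multiplier k(k−1)/2 gives
the pairwise contrasts. For two groups z² equals H exactly, which the
suite asserts to 1e-9.

## Synthetic data generator

The generator emulates a windowed (2004–2023) spontaneous-report extract:

* Each report draws one primary-suspect drug from the catalogue (or a
  non-DMARD background drug), age group, sex, country, reporter type;
  25% add a concomitant drug, 0.2% an excluded co-drug, 30% a brand
  synonym as the raw drug string (half upper-cased) to exercise name
  mapping.
* **Event assignment is logistic**: logit P(PF) = logit(p₀) + ln ROR_drug
  + ln ageOR + ln sexOR(class, male). The injected multipliers are
  therefore odds ratios — exactly what the ROR and the case–non-case
  regression estimate, so recovery is exact in expectation. The ground
  truth also stores the *marginal* ROR implied by the expected 2×2 cells,
  which differs from the injected conditional value when other drugs are
  co-elevated or covariate effects are strong (non-collapsibility).
* **Onset delays** are log-normal per class, parameterised by median and
  IQR (medians 113–523 days, matching the ordering seen in real onset
  data). Therapy starts are drawn so the event lands inside the window,
  as in a real windowed extract; delays longer than the window are capped
  at its length (such reports would simply not be captured). Without this
  windowing, post-2023 event years consist almost entirely of long-delay
  PF cases and the year covariate exhibits spurious complete separation.
* **Duplicates** (default 5%) are emitted half as version-2 rows of the
  same case id and half as new case ids sharing every key variable, to
  exercise both dedup rules. **Missingness** blanks age/sex/country
  independently (defaults 25%/10%/8%, the order of magnitude seen in the
  published case characteristics).

Defaults: background PF reporting rate 0.002 (≈ the published share of PF
among DMARD reports), age odds 1/2/3 across ≤45 / 45–65 / >65, 65%
female, class-specific male-vs-female odds between 0.73 and 1.45. Drug
prevalences among reports are not published anywhere; the catalogue's use
probabilities are deliberate round numbers and are labelled as such.

What the generator does **not** emulate: co-prescription networks,
reporting-rate drift over calendar time, country–drug correlations,
free-text narratives, or the MedDRA hierarchy beyond the packaged term
lists. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to these real-data
features.

## Validation strategy and problem sizes

The published full-database statistics depend on the raw multi-million-
report extract and are not recomputable at desk scale. Instead:

* published descriptive shares, the aggregated-table information
  components, and the signal verdicts are recomputed exactly from printed
  counts;
* ROR and IC are checked against exact-fraction brute force on every 2×2
  table with cells ≤ 30;
* parameter recovery: injected ROR ∈ {1, 2, 4} and age OR 3.0 at
  n = 2×10⁵ reports over 50 seeds, requiring ≥ 90% CI coverage
  (background rate 0.005 in these scenarios so the per-seed cell counts
  make Woolf intervals well calibrated);
* Kruskal–Wallis type-I error is calibrated on 1000 null replicates of
  seven 40-observation groups;
* unit fixtures run at n = 8,000–20,000 reports and pipeline smoke tests
  at n = 12,000 — sizes chosen to keep the full suite fast while leaving
  every count far from small-sample artefacts.

## Known limitations

* Signals are reporting associations; no causal claim is possible from
  spontaneous reports (reporting bias, confounding by indication,
  missing denominators).
* The dedup tie-break (first encountered) and the exact coding of year
  and region are conventions, config-exposed where reasonable.
* Dose and treatment-duration fields are not modelled (not available in
  the source data either).
* Separation is flagged, not corrected (no Firth penalty).
* The aggregated-table reconstruction inherits the rounding of the
  printed RORs (~±0.005 relative), visible in the last digit of some
  recomputed bounds.
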