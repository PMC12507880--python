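# fibrovig

Pharmacovigilance disproportionality analysis of pulmonary fibrosis
associated with disease-modifying antirheumatic drugs (DMARDs), built for
spontaneous-report data: FAERS-style individual case safety reports and
VigiAccess-style aggregated per-drug counts.

Drug-induced pulmonary fibrosis is a rare, severe adverse event whose
association with the 36 DMARDs used in autoimmune disease (conventional
agents such as methotrexate, TNF-α / interleukin / B-cell / T-cell / JAK
/ PDE4-targeted biologics and small molecules) is hard to study outside
large reporting databases. `fibrovig` implements the full signal-detection
path for epidemiologists and drug-safety scientists:

* **ingestion** of quarterly `$`-delimited DEMO/DRUG/REAC/INDI/THER report
  files, with latest-version retention and key-variable deduplication;
* **cohort construction** — brand/synonym → generic drug mapping, MedDRA
  preferred-term case flagging, bleomycin/antifibrotic co-drug exclusion,
  and two comparator designs (full database-wide vs active-comparator
  restricted to autoimmune-indication reports);
* **disproportionality statistics** per drug and per class;
* **case–non-case logistic regression** of reporting on age group and sex;
* **time-to-onset** comparison across drug classes;
* a **synthetic report generator** with known ground truth, so every
  estimator is validated by parameter recovery.

## The statistics

For one drug and the target event, report counts form a 2×2 table with
cells A (event, drug), B (event, other drugs), C (other events, drug),
D (other events, other drugs), N = A+B+C+D. The package computes

* the **reporting odds ratio** ROR = A·D/(B·C), with Woolf 95% CI
  exp(ln ROR ± 1.96·√(1/A + 1/B + 1/C + 1/D));
* the **information component** IC = log₂(A/E) with E = (A+B)(A+C)/N,
  by default BCPNN-style shrunken to log₂((A+½)/(E+½)); its lower 95%
  credibility bound IC025 is the 2.5th percentile of log₂ X,
  X ~ Gamma(shape A+½, rate E+½);
* the **signal criterion**: A ≥ 3 and ROR CI lower bound > 1 and IC025 > 0,
  all simultaneously.

Risk factors use maximum-likelihood logistic regression (Wald intervals),
crude and adjusted for reporting-year bin, region, and the other
demographic. Onset delays (event date − therapy start, days) are trimmed
at the 2.5th/97.5th percentiles and compared with the Kruskal–Wallis test
plus Dunn's Bonferroni-corrected post-hoc contrasts.

## Worked example

Rebuild the aggregated-database signal table from the packaged published
counts (per-drug totals are recovered from each published ROR by
algebraic inversion) and recompute the statistics:

```python
from fibrovig import reference as ref
from fibrovig.cohort import DrugDictionary
from fibrovig.disproportionality import aggregate_signal_table, signal_set

counts = ref.vigiaccess_reconstructed_counts()
table = aggregate_signal_table(counts, ref.VIGIACCESS_PF_CASES,
                               ref.VIGIACCESS_TOTAL_REPORTS,
                               DrugDictionary.from_csv())
print(table[table.signal][["drug", "cases", "ror", "ic", "ic025"]].round(2))
```

prints

```
                     drug  cases    ror    ic  ic025
0            methotrexate   1097   4.39  1.85   1.76
1             leflunomide    138   3.26  1.66   1.41
2           sulfasalazine    101   2.33  1.19   0.90
8           penicillamine     31   5.67  2.38   1.83
9   sodium aurothiomalate     42  13.87  3.56   3.09
10              auranofin     10   2.90  1.41   0.38
17              rituximab    287   1.43  0.49   0.32
25            tocilizumab    142   1.28  0.34   0.10
```

i.e. eight drugs meet all three signal criteria: methotrexate carries the
strongest conventional-DMARD signal (ROR 4.39, IC 1.85 bits — reports are
~3.6× more frequent than expected under independence), and among
biologics only rituximab and tocilizumab signal. Intersecting with the
restricted individual-report analysis leaves five drugs (methotrexate,
leflunomide, sulfasalazine, rituximab, tocilizumab).

The `examples/` directory holds one short script per capability
(aggregated signals, simulate/ingest/dedup, parameter recovery, risk
factors, time-to-onset, full pipeline); each prints its numbers with a
note on what they mean. A thin CLI mirrors the pipeline:
`fibrovig simulate`, `fibrovig signals`, `fibrovig run`.

## Limitations

Disproportionality quantifies reporting associations, not causal risks;
see `docs/methods.md` for the model assumptions, the synthetic-data
design, and known limitations.
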