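"""Time-to-onset comparison across drug classes.

The generator plants log-normal onset delays with class medians spanning
113 days (B-cell inhibitors) to 523 days (TNF-alpha inhibitors). Delays
are trimmed at the 2.5th/97.5th percentiles, compared with the
Kruskal-Wallis test, and contrasted pairwise with Dunn's Bonferroni-
corrected post-hoc test.
"""

from fibrovig.cohort import DrugDictionary, TermLists, build_cohort
from fibrovig.simulate import DrugSpec, ScenarioConfig, generate_reports
from fibrovig.time_to_onset import class_tto_analysis, dunn_posthoc, kruskal_wallis

classes = [("rituximab", "B-cell inhibitors"),
           ("methotrexate", "conventional DMARDs"),
           ("tocilizumab", "interleukin inhibitors"),
           ("etanercept", "TNF-α-targeted inhibitors")]
cfg = ScenarioConfig(
    n_reports=150_000,
    drug_catalog=[DrugSpec(name, label, 0.12) for name, label in classes],
    background_event_rate=0.02,
    true_ror={name: 1.0 for name, _ in classes},
    seed=4,
)
dictionary = DrugDictionary.from_csv()
reports, truth = generate_reports(cfg, dictionary)
cohort = build_cohort(reports, "full_database_wide", dictionary, TermLists.default())
samples, summary = class_tto_analysis(cohort, [label for _, label in classes])
print(summary.round(1).to_string(index=False))
print("true medians:", {k: round(v) for k, v in truth.class_median_onset.items()
                        if k in {label for _, label in classes}})
h, df, p = kruskal_wallis(samples)
print(f"Kruskal-Wallis H={h:.1f} df={df} p={p:.3g}")
print(dunn_posthoc(samples).round(3).to_string(index=False))
# Estimated medians should track the injected 113 < 201 < 234 < 523 day
# ordering; the Kruskal-Wallis p-value is tiny and Dunn flags the pairs
# with well-separated medians after multiplying p by the 6 comparisons.
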