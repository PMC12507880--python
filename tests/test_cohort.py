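"""Drug-name mapping, case flagging, exclusions, designs and imputation."""

import numpy as np
import pytest

from fibrovig.cohort import (DictionaryError, DrugDictionary, TermLists,
                             AnalysisCohort, apply_exclusions, build_cohort,
                             flag_pf_cases, impute_missing, map_drug_names)
from fibrovig.io import DrugEntry, SafetyReport


def _report(case_id, drugs, events=("Nausea",), indications=(), **kw):
    return SafetyReport(case_id=case_id, drugs=list(drugs),
                        events=list(events), indications=list(indications), **kw)


class TestDrugDictionary:
    @pytest.mark.parametrize("raw, expected", [
        ("ENBREL", "etanercept"),
        ("Enbrel 50mg", "etanercept"),
        ("methotrexate sodium", "methotrexate"),
        ("MabThera", "rituximab"),
        ("aspirin", None),
        ("sodium aurothiomalate", "sodium aurothiomalate"),
    ])
    def test_name_matching_policy(self, dictionary, raw, expected):
        assert dictionary.match_name(raw) == expected

    def test_active_ingredient_fallback(self, dictionary):
        assert dictionary.match_name("mystery brand", "tofacitinib citrate") == "tofacitinib"

    def test_all_36_generics_with_classes(self, dictionary):
        assert len(dictionary.generics) == 36
        assert all(g in dictionary.class_map for g in dictionary.generics)

    def test_overlapping_synonyms_rejected_at_load(self):
        with pytest.raises(DictionaryError, match="claimed by both"):
            DrugDictionary(
                entries={"a": {"shared"}, "b": {"Shared"}},
                class_map={"a": "JAK inhibitors", "b": "JAK inhibitors"})

    def test_map_drug_names_shape(self, dictionary):
        reports = [_report("1", [DrugEntry("ENBREL"), DrugEntry("aspirin", role="C")])]
        assert map_drug_names(reports, dictionary) == [["etanercept", None]]


class TestPfFlagging:
    @pytest.mark.parametrize("events, flag", [
        (["Pulmonary fibrosis"], True),
        (["Idiopathic pulmonary fibrosis", "Cough"], True),
        (["Pulmonary embolism"], False),
        (["PULMONARY FIBROSIS"], True),   # case-insensitive
    ])
    def test_event_terms(self, terms, events, flag):
        reports = [_report("1", [DrugEntry("x")], events=events)]
        assert flag_pf_cases(reports, terms) == [flag]


class TestExclusions:
    def test_bleomycin_and_antifibrotics_removed(self, terms):
        reports = [
            _report("pf1", [DrugEntry("methotrexate"), DrugEntry("bleomycin", role="C")],
                    events=["Pulmonary fibrosis"]),
            _report("pf2", [DrugEntry("methotrexate"), DrugEntry("Esbriet", role="C")],
                    events=["Pulmonary fibrosis"]),
            _report("ok", [DrugEntry("methotrexate")]),
        ]
        out = apply_exclusions(reports, terms)
        assert [r.case_id for r in out] == ["ok"]

    def test_filter_is_symmetric_over_non_cases(self, terms):
        # a non-case comparator listing bleomycin is removed too
        reports = [_report("c1", [DrugEntry("atorvastatin"), DrugEntry("Ofev", role="C")])]
        assert apply_exclusions(reports, terms) == []

    def test_never_removes_reports_without_excluded_codrugs(self, clean_reports, terms):
        counts = {}
        out = apply_exclusions(clean_reports, terms, counts)
        assert counts["excluded_codrug_reports"] == 0
        assert out == list(clean_reports)


class TestBuildCohort:
    def test_secondary_suspect_not_exposed(self, dictionary, terms):
        reports = [_report("1", [DrugEntry("adalimumab", role="SS"),
                                 DrugEntry("atorvastatin", role="PS")])]
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        assert cohort.exposures.empty

    def test_autoimmune_indication_comparator_in_restricted(self, dictionary, terms):
        reports = [
            _report("cmp", [DrugEntry("atorvastatin")],
                    indications=["Rheumatoid arthritis"]),
            _report("drop", [DrugEntry("atorvastatin")], indications=["Hypertension"]),
        ]
        cohort = build_cohort(reports, "active_comparator_restricted", dictionary, terms)
        assert list(cohort.reports["case_id"]) == ["cmp"]

    def test_empty_input(self, dictionary, terms):
        cohort = build_cohort([], "full_database_wide", dictionary, terms)
        assert cohort.n_reports == 0 and cohort.n_pf == 0

    def test_unknown_design_rejected(self, dictionary, terms):
        with pytest.raises(ValueError, match="design"):
            build_cohort([], "sideways", dictionary, terms)

    def test_restricted_subset_of_full(self, full_cohort, restricted_cohort):
        assert set(restricted_cohort.reports["case_id"]) <= set(full_cohort.reports["case_id"])

    def test_pf_case_counts_per_drug_equal_across_designs(
            self, full_cohort, restricted_cohort):
        # only the comparator changes between designs
        def counts(c):
            expo = c.exposures
            return expo[expo["is_pf"]].groupby("generic")["case_id"].nunique().to_dict()
        assert counts(full_cohort) == counts(restricted_cohort)

    def test_class_annotation_partitions_exposures(self, full_cohort, dictionary):
        got = dict(zip(full_cohort.exposures["generic"],
                       full_cohort.exposures["class_label"]))
        assert all(dictionary.class_map[g] == lbl for g, lbl in got.items())


class TestImputation:
    def test_none_is_identity(self, restricted_cohort):
        out = impute_missing(restricted_cohort, "none")
        base = [c for c in restricted_cohort.reports.columns]
        assert out.reports[base].equals(restricted_cohort.reports[base])

    def test_unknown_method_fatal(self, restricted_cohort):
        with pytest.raises(ValueError, match="imputation"):
            impute_missing(restricted_cohort, "midway")

    def test_hotdeck_respects_empirical_distribution(self, dictionary, terms):
        reports = ([_report(f"f{i}", [DrugEntry("methotrexate")], sex="F")
                    for i in range(90)]
                   + [_report(f"m{i}", [DrugEntry("methotrexate")], sex="M")
                      for i in range(10)]
                   + [_report(f"u{i}", [DrugEntry("methotrexate")], sex=None)
                      for i in range(60)])
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        female = total = 0
        for seed in range(5):
            out = impute_missing(cohort, "mode_hotdeck", seed=seed)
            filled = out.reports.loc[out.reports["sex_imputed"], "sex"]
            assert not filled.isna().any()
            female += (filled == "F").sum()
            total += len(filled)
        # 90% of observed sex is female: the pooled imputed share stays high
        assert female / total >= 0.8

    def test_fully_observed_unchanged_under_any_method(self, dictionary, terms):
        reports = [_report(f"r{i}", [DrugEntry("methotrexate")], sex="F",
                           age=50.0, country="US", event_date="20150601")
                   for i in range(30)]
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        for method in ("none", "mode_hotdeck", "iterative_model"):
            out = impute_missing(cohort, method, seed=0)
            assert out.reports[["age_group", "sex", "country"]].equals(
                cohort.reports[["age_group", "sex", "country"]])

    def test_iterative_model_fills_everything(self, restricted_cohort):
        out = impute_missing(restricted_cohort, "iterative_model", seed=0)
        assert not out.reports[["age_group", "sex", "country"]].isna().any().any()
        # imputation flags preserved for every originally missing field
        assert out.reports["age_group_imputed"].sum() == \
            restricted_cohort.reports["age_group"].isna().sum()
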