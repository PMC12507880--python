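"""Logistic case–non-case regression against closed-form oracles."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from fibrovig.cohort import build_cohort
from fibrovig.risk_factors import (RankDeficientError, age_sex_analysis,
                                   fit_logistic, results_frame)
from fibrovig.simulate import DrugSpec, ScenarioConfig, generate_reports


def _two_by_two_frame(n00, n01, n10, n11):
    """exposure x outcome counts -> long DataFrame."""
    rows = ([(0, 0)] * n00 + [(0, 1)] * n01 + [(1, 0)] * n10 + [(1, 1)] * n11)
    df = pd.DataFrame(rows, columns=["x", "y"])
    X = pd.DataFrame({"const": 1.0, "x": df["x"].astype(float)})
    return X, df["y"].to_numpy()


class TestFitLogistic:
    def test_univariable_equals_cross_product_ratio(self):
        # closed form: OR = (n00*n11)/(n01*n10)
        n00, n01, n10, n11 = 400, 25, 300, 60
        X, y = _two_by_two_frame(n00, n01, n10, n11)
        fit = fit_logistic(X, y)
        or_, lo, hi, p = fit.odds_ratio("x")
        assert or_ == pytest.approx((n00 * n11) / (n01 * n10), rel=1e-6)
        assert lo < or_ < hi

    def test_wald_interval_matches_woolf_se(self):
        n00, n01, n10, n11 = 400, 25, 300, 60
        X, y = _two_by_two_frame(n00, n01, n10, n11)
        fit = fit_logistic(X, y)
        _, lo, hi, _ = fit.odds_ratio("x")
        se = math.sqrt(1 / n00 + 1 / n01 + 1 / n10 + 1 / n11)
        or_ = (n00 * n11) / (n01 * n10)
        assert lo == pytest.approx(or_ * math.exp(-1.96 * se), rel=1e-3)
        assert hi == pytest.approx(or_ * math.exp(1.96 * se), rel=1e-3)

    def test_all_zero_outcomes_flagged_non_estimable(self):
        X, y = _two_by_two_frame(50, 0, 50, 0)
        fit = fit_logistic(X, y)
        assert fit.separation and not fit.converged

    def test_complete_separation_flagged(self):
        X, y = _two_by_two_frame(100, 0, 0, 100)
        fit = fit_logistic(X, y)
        assert fit.separation

    def test_rank_deficiency_names_column(self):
        X, y = _two_by_two_frame(50, 10, 40, 20)
        X["x_copy"] = X["x"]
        with pytest.raises(RankDeficientError, match="x_copy|x"):
            fit_logistic(X, y)

    def test_type_one_error_calibration_under_null(self):
        """Outcome independent of covariate: |beta| < 3*se almost always."""
        rng = np.random.default_rng(12)
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.integers(0, 2, size=10_000)
            y = rng.random(10_000) < 0.05
            X = pd.DataFrame({"const": 1.0, "x": x.astype(float)})
            fit = fit_logistic(X, y)
            beta = fit.params["x"]
            se = math.sqrt(fit.cov.loc["x", "x"])
            hits += abs(beta) < 3 * se
        assert hits / reps >= 0.95


def _class_scenario(n, seed, age_effect, sex_effect, ror=3.2, bg=0.01):
    return ScenarioConfig(
        n_reports=n,
        drug_catalog=[DrugSpec("methotrexate", "conventional DMARDs", 0.15),
                      DrugSpec("leflunomide", "conventional DMARDs", 0.15)],
        background_event_rate=bg,
        true_ror={"methotrexate": ror, "leflunomide": ror},
        age_effect=age_effect,
        sex_effect=sex_effect,
        seed=seed)


class TestAgeSexAnalysis:
    def test_recovers_injected_age_odds_ratio(self, dictionary, terms):
        """Class-scale scenario with true OR(>65 vs <=45) = 3.2."""
        cfg = _class_scenario(200_000, 21,
                              age_effect={"<=45": 1.0, "45-65": 2.0, ">65": 3.2},
                              sex_effect={})
        reports, _ = generate_reports(cfg, dictionary)
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        res = results_frame(age_sex_analysis(cohort, "conventional DMARDs"))
        row = res[(res.analysis == "age") & (res.stratum == ">65")].iloc[0]
        assert 2.7 < row.or_adjusted < 3.8
        assert row.adj_low < 3.2 < row.adj_high

    def test_recovers_injected_sex_effect_within_15_percent(self, dictionary, terms):
        cfg = _class_scenario(200_000, 22,
                              age_effect={"<=45": 1.0, "45-65": 1.0, ">65": 1.0},
                              sex_effect={"conventional DMARDs": 1.5})
        reports, _ = generate_reports(cfg, dictionary)
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        res = results_frame(age_sex_analysis(cohort, "conventional DMARDs"))
        row = res[res.analysis == "sex"].iloc[0]
        assert abs(row.or_adjusted - 1.5) / 1.5 <= 0.15

    def test_crude_equals_adjusted_when_covariates_independent(self, dictionary, terms):
        # generator draws year/region/sex independent of age
        cfg = _class_scenario(60_000, 23,
                              age_effect={"<=45": 1.0, "45-65": 1.0, ">65": 2.5},
                              sex_effect={})
        reports, _ = generate_reports(cfg, dictionary)
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        res = results_frame(age_sex_analysis(cohort, "conventional DMARDs"))
        row = res[(res.analysis == "age") & (res.stratum == ">65")].iloc[0]
        assert row.or_adjusted == pytest.approx(row.or_crude, rel=0.10)

    def test_zero_case_stratum_reported_non_estimable(self, dictionary, terms):
        cfg = dataclasses.replace(
            _class_scenario(3_000, 24, {"<=45": 1.0, "45-65": 1.0, ">65": 1.0}, {}),
            background_event_rate=0.0)
        reports, _ = generate_reports(cfg, dictionary)
        cohort = build_cohort(reports, "full_database_wide", dictionary, terms)
        res = results_frame(age_sex_analysis(cohort, "conventional DMARDs"))
        assert not res["estimable"].any()
        assert res["or_adjusted"].isna().all()
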