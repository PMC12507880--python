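"""Case–non-case logistic regression of event reporting on age and sex.

Within the reports of one DMARD class, target-event reports are treated
as cases and all other reports of that class as non-cases. Reporting
odds ratios for age group (reference ≤45) and sex (reference female) are
estimated crude (exposure only) and adjusted — for reporting year
(5-year bins), region (continent roll-up of the reporting country), sex
in the age analysis and age in the sex analysis. Estimation is maximum
likelihood via iteratively reweighted least squares; intervals are Wald,
``exp(β ± 1.96·se)``.

These are reporting associations within a spontaneous-report database,
not causal effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sp_stats

from .cohort import AGE_GROUPS, AnalysisCohort

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054
SEPARATION_BETA = 15.0  # |beta| beyond this flags (quasi-)complete separation

YEAR_BINS = list(range(2004, 2044, 5))  # 5-year reporting-period bins


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; the message names a column."""


@dataclass(slots=True)
class LogisticFit:
    """Coefficients, covariance and diagnostics of one logistic fit."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    separation: bool
    n_obs: int

    def odds_ratio(self, term: str) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, two-sided Wald p) for one coefficient."""
        beta = self.params[term]
        se = float(np.sqrt(self.cov.loc[term, term]))
        p = 2.0 * float(sp_stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
        return (float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
                float(np.exp(beta + Z95 * se)), p)


@dataclass(slots=True)
class RiskFactorResult:
    """Crude and adjusted reporting odds ratios for one stratum."""

    class_label: str
    analysis: str             # 'age' or 'sex'
    stratum: str              # e.g. '45-65', '>65', 'M'
    n_cases: int
    n_noncases: int
    or_crude: float
    crude_ci: tuple[float, float]
    or_adjusted: float
    adjusted_ci: tuple[float, float]
    p_value: float
    estimable: bool = True


def fit_logistic(X: pd.DataFrame, y, max_iter: int = 50,
                 tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with Wald covariance.

    ``X`` must already contain the intercept column. Rank deficiency is
    fatal and names the offending column; separation (any |β| above 15,
    or non-convergence) is flagged so callers can report the stratum as
    non-estimable rather than quoting an absurd interval.
    """
    X = X.astype(float)
    y = np.asarray(y, dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name one column whose removal restores full rank
        for col in X.columns:
            reduced = X.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise RankDeficientError(f"design matrix is rank deficient at column {col!r}")
        raise RankDeficientError("design matrix is rank deficient")
    if y.min() == y.max():
        # degenerate outcome: no information about any coefficient
        nan = pd.Series(np.nan, index=X.columns)
        return LogisticFit(params=nan, cov=pd.DataFrame(np.nan, index=X.columns,
                                                        columns=X.columns),
                           converged=False, separation=True, n_obs=len(y))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol)
    converged = bool(getattr(res, "converged", True))
    separation = bool(np.max(np.abs(res.params.to_numpy())) > SEPARATION_BETA) or not converged
    return LogisticFit(params=res.params, cov=res.cov_params(),
                       converged=converged, separation=separation, n_obs=len(y))


def _bin_year(years: pd.Series) -> pd.Series:
    binned = pd.cut(pd.to_numeric(years, errors="coerce"),
                    bins=YEAR_BINS, right=False)
    return binned.astype(str).where(binned.notna(), None)


MIN_LEVEL_COUNT = 30  # adjustment levels rarer than this merge into the reference


def _design(df: pd.DataFrame, exposure: str, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for col in [exposure] + covariates:
        dummies = pd.get_dummies(df[col], prefix=col, drop_first=False, dtype=float)
        ref = _reference_level(col, dummies)
        dummies = dummies.drop(columns=[ref])
        # empty exposure levels are dropped; rare adjustment levels are
        # merged into the reference so a near-empty stratum cannot cause
        # spurious quasi-separation of the whole fit
        min_count = 1 if col == exposure else MIN_LEVEL_COUNT
        dummies = dummies.loc[:, dummies.sum(axis=0) >= min_count]
        X = X.join(dummies)
    return X


def _reference_level(col: str, dummies: pd.DataFrame) -> str:
    if col == "age_group":
        return f"{col}_{AGE_GROUPS[0]}"
    if col == "sex":
        return f"{col}_F"
    return dummies.columns[0]  # first observed level for year/region


def age_sex_analysis(cohort: AnalysisCohort, class_label: str,
                     adjust: bool = True) -> list[RiskFactorResult]:
    """Fig-style age and sex risk-factor analysis for one DMARD class.

    Complete-case on the covariates involved (run ``impute_missing``
    beforehand to reproduce an imputed analysis). Returns one result per
    non-reference stratum; strata with zero cases are emitted as
    non-estimable NA rows.
    """
    case_ids = set(cohort.class_exposures(class_label)["case_id"])
    df = cohort.reports[cohort.reports["case_id"].isin(case_ids)].copy()
    df["year_bin"] = _bin_year(df["year"])
    out: list[RiskFactorResult] = []
    for analysis, exposure, strata in (
            ("age", "age_group", [g for g in AGE_GROUPS[1:]]),
            ("sex", "sex", ["M"])):
        covariates = ["year_bin", "region"] + (["sex"] if analysis == "age" else ["age_group"])
        needed = [exposure] + (covariates if adjust else [])
        sub = df.dropna(subset=[c for c in needed if c in df.columns])
        crude_fit = adj_fit = None
        if not sub.empty and sub[exposure].nunique() > 1:
            y = sub["is_pf"].astype(float).to_numpy()
            crude_fit = fit_logistic(_design(sub, exposure, []), y)
            adj_fit = (fit_logistic(_design(sub, exposure, covariates), y)
                       if adjust else crude_fit)
        for stratum in strata:
            term = f"{exposure}_{stratum}"
            in_stratum = sub[exposure] == stratum if not sub.empty else pd.Series(dtype=bool)
            n_cases = int(sub.loc[in_stratum, "is_pf"].sum()) if not sub.empty else 0
            n_non = int((~sub.loc[in_stratum, "is_pf"].astype(bool)).sum()) if not sub.empty else 0
            ok = (crude_fit is not None and term in crude_fit.params.index
                  and not crude_fit.separation and not adj_fit.separation
                  and n_cases > 0)
            if not ok:
                out.append(RiskFactorResult(
                    class_label, analysis, stratum, n_cases, n_non,
                    np.nan, (np.nan, np.nan), np.nan, (np.nan, np.nan),
                    np.nan, estimable=False))
                continue
            orc, orc_lo, orc_hi, _ = crude_fit.odds_ratio(term)
            ora, ora_lo, ora_hi, p = adj_fit.odds_ratio(term)
            out.append(RiskFactorResult(
                class_label, analysis, stratum, n_cases, n_non,
                orc, (orc_lo, orc_hi), ora, (ora_lo, ora_hi), p))
    return out


def results_frame(results: list[RiskFactorResult]) -> pd.DataFrame:
    """Tidy DataFrame mirroring the per-class forest-plot layout."""
    rows = [(r.class_label, r.analysis, r.stratum, r.n_cases, r.n_noncases,
             r.or_crude, r.crude_ci[0], r.crude_ci[1],
             r.or_adjusted, r.adjusted_ci[0], r.adjusted_ci[1],
             r.p_value, r.estimable) for r in results]
    return pd.DataFrame(rows, columns=[
        "class", "analysis", "stratum", "n_cases", "n_noncases",
        "or_crude", "crude_low", "crude_high",
        "or_adjusted", "adj_low", "adj_high", "p_value", "estimable",
    ])
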