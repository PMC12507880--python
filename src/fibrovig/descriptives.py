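"""Descriptive summaries of target-event cases.

Characteristic tables count cases by age group, sex, country and
reporter type, per drug class and overall. Percentages are computed
among *known* values only; unknown counts are reported as their own
rows — the convention under which the published shares (e.g. the
female share of cases) reproduce exactly from the printed counts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, AnalysisCohort

UNKNOWN = "Unknown"


def shares_among_known(counts: Mapping[str, float]) -> dict[str, float]:
    """Percentage share of each stratum among known (non-Unknown) counts."""
    known = {k: v for k, v in counts.items() if k != UNKNOWN}
    total = sum(known.values())
    if total == 0:
        return {k: float("nan") for k in known}
    return {k: 100.0 * v / total for k, v in known.items()}


def class_shares_from_counts(class_counts: Mapping[str, float]) -> dict[str, float]:
    """Each class's percentage of the total case count."""
    total = sum(class_counts.values())
    if total == 0:
        return {k: float("nan") for k in class_counts}
    return {k: 100.0 * v / total for k, v in class_counts.items()}


def _variable_counts(df: pd.DataFrame, column: str, order: list[str]) -> dict[str, int]:
    counts = {}
    series = df[column]
    for level in order:
        counts[level] = int((series == level).sum())
    counts[UNKNOWN] = int(series.isna().sum())
    return counts


def summarize_cases(cohort: AnalysisCohort) -> pd.DataFrame:
    """Characteristic table of target-event cases, per class and overall.

    One row per (variable, stratum, column); ``pct`` is the share among
    known values, NaN on Unknown rows. A case suspected of drugs from two
    classes appears in both class columns but once in Overall.
    """
    cases = cohort.reports[cohort.reports["is_pf"]]
    class_cases = cohort.exposures[cohort.exposures["is_pf"]]
    columns = {"Overall": cases}
    for label in sorted(class_cases["class_label"].unique()):
        ids = set(class_cases.loc[class_cases["class_label"] == label, "case_id"])
        columns[label] = cases[cases["case_id"].isin(ids)]

    variables = [
        ("age", "age_group", list(AGE_GROUPS)),
        ("sex", "sex", ["F", "M"]),
        ("country", "country", None),
        ("reporter", "reporter", ["health-professional", "consumer"]),
    ]
    rows = []
    for col_name, df in columns.items():
        rows.append(("total", "all", col_name, len(df), np.nan))
        for var, column, order in variables:
            levels = order if order is not None else sorted(
                x for x in df[column].dropna().unique())
            counts = _variable_counts(df, column, levels)
            pct = shares_among_known(counts)
            for level in levels:
                rows.append((var, level, col_name, counts[level], pct.get(level, np.nan)))
            rows.append((var, UNKNOWN, col_name, counts[UNKNOWN], np.nan))
    return pd.DataFrame(rows, columns=["variable", "stratum", "column", "count", "pct"])


def class_shares(cohort: AnalysisCohort) -> pd.DataFrame:
    """Per-class case counts and their percentage of all target-event cases."""
    class_cases = cohort.exposures[cohort.exposures["is_pf"]]
    if class_cases.empty:
        return pd.DataFrame(columns=["class", "n", "share_pct"])
    counts = class_cases.groupby("class_label")["case_id"].nunique()
    total = cohort.n_pf
    rows = [(label, int(n), round(100.0 * n / total, 2))
            for label, n in counts.sort_values(ascending=False).items()]
    return pd.DataFrame(rows, columns=["class", "n", "share_pct"])


def annual_trend(cohort: AnalysisCohort) -> pd.DataFrame:
    """Per-year target-event counts among exposed reports and their share.

    Years come from the event date. Years inside the observed span with
    no reports at all still appear, with zero counts.
    """
    exposed_ids = set(cohort.exposures["case_id"])
    df = cohort.reports[cohort.reports["case_id"].isin(exposed_ids)]
    df = df[df["year"].notna()]
    if df.empty:
        return pd.DataFrame(columns=["year", "n_pf", "n_reports", "proportion"])
    years = df["year"].astype(int)
    lo, hi = years.min(), years.max()
    rows = []
    for year in range(lo, hi + 1):
        sub = df[years == year]
        n_all = len(sub)
        n_pf = int(sub["is_pf"].sum())
        rows.append((year, n_pf, n_all, n_pf / n_all if n_all else 0.0))
    return pd.DataFrame(rows, columns=["year", "n_pf", "n_reports", "proportion"])
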