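"""Disproportionality statistics: ROR, information component, signals.

For one drug and one target event, report counts form a 2×2 table

=============  ============  ===============
               target event  other events
=============  ============  ===============
drug           a             c
all other      b             d
=============  ============  ===============

The reporting odds ratio is the cross-product ratio ``ROR = a·d / (b·c)``
with a Woolf (log-normal) 95% confidence interval,
``exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))``.

The information component compares the observed count against the count
expected under independence of the drug and event margins,
``E = (a+b)(a+c)/n`` and ``IC = log2(a/E)``. The default applies the
BCPNN-style +0.5 shrinkage, ``IC = log2((a+0.5)/(E+0.5))``, which keeps
the statistic finite at a = 0 and damps small-count noise. Its lower 95%
credibility bound ``IC025`` is the 2.5th percentile of ``log2(X)`` where
``X ~ Gamma(shape = a + 0.5, rate = E + 0.5)`` — the posterior of the
observed/expected ratio under a Poisson count with that shrinkage prior.

A drug is a *signal* when simultaneously: at least 3 target-event
reports, the ROR CI lower bound exceeds 1, and IC025 exceeds 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisCohort, DrugDictionary
from .io import AggregatedCounts

Z95 = 1.959963984540054  # two-sided 95% normal quantile

MIN_CASES = 3  # signal criterion (c)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2×2 report counts for one drug × one event."""

    a: int  # target-event reports, target drug
    b: int  # target-event reports, all other reports
    c: int  # other-event reports, target drug
    d: int  # other-event reports, all other reports

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")
        if self.n == 0:
            raise ValueError("empty 2x2 table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected target-drug event count under margin independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float


class IcResult(NamedTuple):
    ic: float
    ic025: float
    expected: float


@dataclass(slots=True)
class SignalStats:
    """Disproportionality summary and verdict for one drug."""

    drug: str
    class_label: str | None
    n_cases: int
    ror: float
    ror_ci: tuple[float, float]
    ic: float
    ic025: float
    expected: float
    signal: bool


def compute_ror(table: ContingencyTable, continuity: float = 0.0) -> RorResult:
    """Cross-product ratio with Woolf 95% CI.

    A zero cell leaves the ratio undefined: all three values are NaN
    unless a Haldane–Anscombe ``continuity`` correction (typically 0.5)
    is requested, in which case it is added to every cell.
    """
    a, b, c, d = (table.a + continuity, table.b + continuity,
                  table.c + continuity, table.d + continuity)
    if min(a, b, c, d) <= 0:
        return RorResult(math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def compute_ic(table: ContingencyTable, shrinkage: bool = True,
               ic025_method: str = "gamma", n_mc: int = 100_000,
               rng: np.random.Generator | None = None) -> IcResult:
    """Information component and its lower 95% credibility bound.

    With ``shrinkage`` off, ``IC = log2(a/E)`` exactly as defined and is
    undefined (NaN) at a = 0. The credibility bound always uses the
    shrunken Gamma posterior (shape a+0.5, rate E+0.5); set
    ``ic025_method='mc'`` to draw it by Monte Carlo instead of the
    closed-form quantile, or ``'skip'`` to omit it in bulk loops.
    """
    expected = table.expected
    if shrinkage:
        ic = math.log2((table.a + 0.5) / (expected + 0.5))
    else:
        ic = math.log2(table.a / expected) if table.a > 0 and expected > 0 else math.nan
    shape, rate = table.a + 0.5, expected + 0.5
    if ic025_method == "gamma":
        q = stats.gamma.ppf(0.025, shape, scale=1.0 / rate)
    elif ic025_method == "mc":
        rng = rng if rng is not None else np.random.default_rng(0)
        q = np.quantile(rng.gamma(shape, 1.0 / rate, size=n_mc), 0.025)
    elif ic025_method == "skip":
        return IcResult(ic, math.nan, expected)
    else:
        raise ValueError(f"unknown ic025_method {ic025_method!r}")
    return IcResult(ic, math.log2(q), expected)


def evaluate_signal(stats_: SignalStats) -> bool:
    """Apply the three signal criteria simultaneously."""
    low = stats_.ror_ci[0]
    return bool(stats_.n_cases >= MIN_CASES
                and not math.isnan(low) and low > 1.0
                and not math.isnan(stats_.ic025) and stats_.ic025 > 0.0)


# ---------------------------------------------------------------------------
# table construction


def build_contingency(cohort: AnalysisCohort, drug: str,
                      dictionary: DrugDictionary | None = None) -> ContingencyTable:
    """Per-drug 2×2 table from an annotated cohort.

    a/c count reports with the drug as primary suspect; b/d count the
    cohort's remaining reports (the comparator population fixed by the
    cohort's design).
    """
    if dictionary is not None and drug not in dictionary.entries:
        raise KeyError(f"drug {drug!r} not in dictionary")
    expo = cohort.exposures
    drug_rows = expo[expo["generic"] == drug]
    n_drug = drug_rows["case_id"].nunique()
    a = drug_rows.loc[drug_rows["is_pf"], "case_id"].nunique()
    total = cohort.n_reports
    total_pf = cohort.n_pf
    c = n_drug - a
    b = total_pf - a
    d = total - total_pf - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def build_class_contingency(cohort: AnalysisCohort, class_label: str) -> ContingencyTable:
    """Class-level table: member drugs' exposed reports pooled before counting."""
    expo = cohort.class_exposures(class_label)
    n_drug = expo["case_id"].nunique()
    a = expo.loc[expo["is_pf"], "case_id"].nunique()
    total, total_pf = cohort.n_reports, cohort.n_pf
    c = n_drug - a
    return ContingencyTable(a=a, b=total_pf - a, c=c, d=total - total_pf - c)


def table_from_aggregates(counts: AggregatedCounts, total_event: int,
                          total_reports: int) -> ContingencyTable:
    """2×2 table from aggregated per-drug counts and database totals."""
    a = counts.n_event
    c = counts.n_total - counts.n_event
    b = total_event - a
    d = total_reports - total_event - c
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"negative derived cell for {counts.drug!r}: a={a}, b={total_event}-{a}={b}, "
            f"c={counts.n_total}-{a}={c}, d={total_reports}-{total_event}-{c}={d}")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def backsolve_drug_total(n_event: int, ror: float, total_event: int,
                         total_reports: int) -> int:
    """Recover a drug's total report count from its printed ROR.

    Inverts ``ROR = a·d/(b·c)`` with ``a = n_event``, ``b = total_event −
    a`` and ``c + d = total_reports − total_event``:
    ``c = a·(N − A − B)/(A + ROR·B)``. Useful when an aggregated source
    prints per-drug event counts and the ROR but not per-drug totals.
    """
    a = n_event
    b = total_event - a
    if a <= 0 or ror <= 0:
        raise ValueError("back-solving requires a positive event count and ROR")
    c = a * (total_reports - total_event) / (a + ror * b)
    return a + int(round(c))


# ---------------------------------------------------------------------------
# result tables and signal sets


def _stats_for_table(drug: str, class_label: str | None, table: ContingencyTable,
                     continuity: float = 0.0, ic025_method: str = "gamma") -> SignalStats:
    ror = compute_ror(table, continuity=continuity)
    ic = compute_ic(table, ic025_method=ic025_method)
    s = SignalStats(
        drug=drug, class_label=class_label, n_cases=table.a,
        ror=ror.ror, ror_ci=(ror.ci_low, ror.ci_high),
        ic=ic.ic, ic025=ic.ic025, expected=ic.expected, signal=False,
    )
    s.signal = evaluate_signal(s)
    return s


def drug_signal_table(cohort: AnalysisCohort, dictionary: DrugDictionary,
                      drugs: Sequence[str] | None = None,
                      continuity: float = 0.0,
                      ic025_method: str = "gamma") -> pd.DataFrame:
    """Per-drug disproportionality results over a cohort.

    One row per drug with case count, ROR and CI, IC and IC025, and the
    signal verdict. Statistics that are undefined (zero cells) are NaN,
    rendered as NA on export.
    """
    drugs = list(drugs) if drugs is not None else dictionary.generics
    rows = []
    for drug in drugs:
        table = build_contingency(cohort, drug, dictionary)
        s = _stats_for_table(drug, dictionary.class_map.get(drug), table,
                             continuity, ic025_method)
        rows.append((s.drug, s.class_label, s.n_cases, s.ror, s.ror_ci[0],
                     s.ror_ci[1], s.ic, s.ic025, s.expected, s.signal))
    return pd.DataFrame(rows, columns=[
        "drug", "class", "cases", "ror", "ci_low", "ci_high",
        "ic", "ic025", "expected", "signal",
    ])


def class_signal_table(cohort: AnalysisCohort, dictionary: DrugDictionary,
                       continuity: float = 0.0) -> pd.DataFrame:
    """Class-level disproportionality results (member drugs pooled)."""
    labels = sorted(set(dictionary.class_map.values()))
    rows = []
    for label in labels:
        table = build_class_contingency(cohort, label)
        s = _stats_for_table(label, label, table, continuity)
        rows.append((label, s.n_cases, s.ror, s.ror_ci[0], s.ror_ci[1],
                     s.ic, s.ic025, s.signal))
    return pd.DataFrame(rows, columns=[
        "class", "cases", "ror", "ci_low", "ci_high", "ic", "ic025", "signal",
    ])


def aggregate_signal_table(counts: Iterable[AggregatedCounts], total_event: int,
                           total_reports: int,
                           dictionary: DrugDictionary | None = None) -> pd.DataFrame:
    """Disproportionality results from aggregated per-drug counts."""
    rows = []
    for cnt in counts:
        table = table_from_aggregates(cnt, total_event, total_reports)
        label = dictionary.class_map.get(cnt.drug) if dictionary is not None else None
        s = _stats_for_table(cnt.drug, label, table)
        rows.append((s.drug, s.class_label, s.n_cases, s.ror, s.ror_ci[0],
                     s.ror_ci[1], s.ic, s.ic025, s.expected, s.signal))
    return pd.DataFrame(rows, columns=[
        "drug", "class", "cases", "ror", "ci_low", "ci_high",
        "ic", "ic025", "expected", "signal",
    ])


def signals_from_printed(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the signal criteria to an already-computed results table.

    Expects columns ``cases``, ``ci_low`` and ``ic025`` (e.g. a published
    signal table); returns a copy with a boolean ``signal`` column.
    """
    out = df.copy()
    out["signal"] = (
        (out["cases"].astype(float) >= MIN_CASES)
        & (pd.to_numeric(out["ci_low"], errors="coerce") > 1.0)
        & (pd.to_numeric(out["ic025"], errors="coerce") > 0.0)
    )
    return out


def signal_set(results: pd.DataFrame | Iterable[SignalStats]) -> set[str]:
    """Names of signal-positive drugs from a results table or stats list."""
    if isinstance(results, pd.DataFrame):
        return set(results.loc[results["signal"].astype(bool), "drug"])
    return {s.drug for s in results if s.signal}


def intersect_signal_sets(*sets: Iterable[str]) -> list[str]:
    """Sorted intersection of signal sets across analyses."""
    sets = [set(s) for s in sets]
    if not sets:
        return []
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return sorted(out)
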