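"""Published reference tables and database totals packaged with fibrovig.

The packaged CSVs transcribe the published per-drug signal tables
(case counts, ROR with 95% CI, IC with IC025) for the two source
databases, and the published case-characteristic counts. They serve as
printed-number inputs: per-drug report totals are not published for the
aggregated database, but can be recovered from each printed ROR by
algebraic inversion (see :func:`vigiaccess_reconstructed_counts`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .disproportionality import backsolve_drug_total
from .io import AggregatedCounts

# database totals, as published
FAERS_TOTAL_RAW_REPORTS = 20_755_634      # before version retention / dedup
FAERS_TOTAL_UNIQUE_REPORTS = 17_233_136   # full-database comparator population
FAERS_AUTOIMMUNE_REPORTS = 3_560_168      # autoimmune-restricted population
FAERS_DMARD_REPORTS = 2_456_021           # reports with a DMARD as primary suspect
FAERS_PF_CASES = 4_869                    # target-event cases among DMARD reports
VIGIACCESS_TOTAL_REPORTS = 3_488_917      # aggregated DMARD reports
VIGIACCESS_PF_CASES = 4_847               # target-event cases among them


def _read(name: str) -> pd.DataFrame:
    with resources.files("fibrovig.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_vigiaccess_signals() -> pd.DataFrame:
    """Published aggregated-database signal table (36 drugs)."""
    return _read("vigiaccess_signals.csv")


def load_faers_restricted_signals() -> pd.DataFrame:
    """Published active-comparator-restricted signal table (36 drugs)."""
    return _read("faers_restricted_signals.csv")


def load_faers_full_signals() -> pd.DataFrame:
    """Published full-database-wide signal table (36 drugs)."""
    return _read("faers_full_signals.csv")


def load_case_characteristics() -> pd.DataFrame:
    """Published case-characteristic counts (overall and per class)."""
    return _read("case_characteristics.csv")


def vigiaccess_reconstructed_counts() -> list[AggregatedCounts]:
    """Aggregated per-drug counts with totals back-solved from printed RORs.

    Drugs whose ROR is unpublished (zero cases) are skipped: their totals
    cannot be recovered.
    """
    df = load_vigiaccess_signals()
    out = []
    for row in df.itertuples(index=False):
        if pd.isna(row.ror) or row.cases <= 0:
            continue
        n_total = backsolve_drug_total(
            int(row.cases), float(row.ror),
            VIGIACCESS_PF_CASES, VIGIACCESS_TOTAL_REPORTS)
        out.append(AggregatedCounts(drug=row.drug, n_event=int(row.cases),
                                    n_total=n_total))
    return out
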