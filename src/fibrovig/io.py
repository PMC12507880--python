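"""Reading, writing and normalising spontaneous-report files.

Individual case safety reports arrive as quarterly sets of $-delimited
ASCII tables (DEMO/DRUG/REAC/INDI/THER record types, one row per
demographic record, drug mention, reaction term, indication term or
therapy episode). This module joins those record types into
:class:`SafetyReport` objects, normalises ages and dates, retains the
latest version of each case and removes key-variable duplicates.
Aggregated per-drug count tables (VigiAccess-style) are read separately.

Dates are kept as normalised digit strings (``YYYYMMDD``, ``YYYYMM`` or
``YYYY``). Partial dates participate in deduplication but are unusable
for time-to-onset, which requires day resolution.
"""

from __future__ import annotations

import glob
import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLE_CODES = ("PS", "SS", "C", "I")  # primary suspect, secondary suspect, concomitant, interacting

#: multiplicative factors converting a stated age unit to years
AGE_UNIT_TO_YEARS: Mapping[str, float] = {
    "YR": 1.0,
    "YEAR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

MAX_PLAUSIBLE_AGE = 120.0

REPORTER_CODES = {
    "MD": "health-professional",
    "PH": "health-professional",
    "RN": "health-professional",
    "OT": "health-professional",
    "HP": "health-professional",
    "CN": "consumer",
    "LW": "consumer",
}


class IngestError(RuntimeError):
    """Fatal problem with an input file (missing column, bad counts)."""


@dataclass(slots=True)
class DrugEntry:
    """One drug mention on a report."""

    name_raw: str
    active_ingredient: str | None = None
    role: str = "PS"
    therapy_start: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role {self.role!r}; expected one of {ROLE_CODES}")


@dataclass(slots=True)
class SafetyReport:
    """One individual case safety report (one case version)."""

    case_id: str
    version: int = 1
    event_date: str | None = None
    age: float | None = None
    sex: str | None = None          # 'F' / 'M'
    country: str | None = None
    reporter: str | None = None     # 'health-professional' / 'consumer'
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def dedup_key(self) -> tuple:
        """Key-variable tuple: age, sex, country, drug set, event set, event date.

        Absent fields compare equal to absent, so two reports with the
        same knowns and the same unknowns collapse to one.
        """
        age = None if self.age is None else round(self.age, 2)
        drugs = tuple(sorted({d.name_raw.strip().lower() for d in self.drugs}))
        events = tuple(sorted({e.strip().lower() for e in self.events}))
        return (age, self.sex, self.country, drugs, events, self.event_date)


@dataclass(slots=True)
class AggregatedCounts:
    """Aggregated per-drug counts: target-event reports and total reports."""

    drug: str
    n_event: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_event < 0 or self.n_total < 0:
            raise IngestError(f"negative count for {self.drug!r}: {self.n_event}/{self.n_total}")
        if self.n_event > self.n_total:
            raise IngestError(
                f"row {self.drug!r}: n_event {self.n_event} exceeds n_total {self.n_total}"
            )


@dataclass
class DialectConfig:
    """Column maps for one era of the $-delimited quarterly layout.

    Each map translates the internal field name to the column header used
    in the files; unknown extra columns are ignored.
    """

    delimiter: str = "$"
    demo: dict[str, str] = field(default_factory=lambda: {
        "case_id": "caseid", "version": "caseversion", "event_date": "event_dt",
        "age": "age", "age_unit": "age_cod", "sex": "sex",
        "country": "reporter_country", "reporter": "occp_cod",
    })
    drug: dict[str, str] = field(default_factory=lambda: {
        "case_id": "caseid", "version": "caseversion", "seq": "drug_seq",
        "role": "role_cod", "name": "drugname", "active_ingredient": "prod_ai",
    })
    reac: dict[str, str] = field(default_factory=lambda: {
        "case_id": "caseid", "version": "caseversion", "term": "pt",
    })
    indi: dict[str, str] = field(default_factory=lambda: {
        "case_id": "caseid", "version": "caseversion", "term": "indi_pt",
    })
    ther: dict[str, str] = field(default_factory=lambda: {
        "case_id": "caseid", "version": "caseversion", "seq": "dsg_drug_seq",
        "start": "start_dt",
    })


@dataclass
class IngestLog:
    """Counters accumulated across an ingestion run.

    ``reports_in == reports_out + versions_dropped + key_duplicates_dropped``
    holds after version retention and key-variable deduplication.
    """

    files_read: int = 0
    reports_in: int = 0
    rows_skipped: int = 0
    version_conflicts: int = 0
    versions_dropped: int = 0
    key_duplicates_dropped: int = 0


# ---------------------------------------------------------------------------
# field normalisers


def normalize_age(value, unit) -> float | None:
    """Convert a stated (age, unit) pair to years; implausible values -> None."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        raw = float(value)
    except (TypeError, ValueError):
        return None
    unit_key = str(unit).strip().upper() if unit is not None and not pd.isna(unit) else "YR"
    factor = AGE_UNIT_TO_YEARS.get(unit_key)
    if factor is None:
        return None
    years = raw * factor
    if years <= 0 or years > MAX_PLAUSIBLE_AGE:
        return None
    return years


def normalize_date(value) -> str | None:
    """Normalise to a digit string of length 8 (day), 6 (month) or 4 (year)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s.endswith(".0"):
        s = s[:-2]
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return None
    return s


def parse_day(date_str: str | None) -> pd.Timestamp | None:
    """Day-resolution timestamp, or None for partial/absent dates."""
    if date_str is None or len(date_str) != 8:
        return None
    try:
        return pd.Timestamp(f"{date_str[:4]}-{date_str[4:6]}-{date_str[6:8]}")
    except ValueError:
        return None


def _normalize_sex(value) -> str | None:
    s = str(value).strip().upper() if value is not None and not pd.isna(value) else ""
    return s if s in ("F", "M") else None


def _normalize_reporter(value) -> str | None:
    if value is None or pd.isna(value):
        return None
    s = str(value).strip()
    if s in ("health-professional", "consumer"):
        return s
    return REPORTER_CODES.get(s.upper())


# ---------------------------------------------------------------------------
# quarterly-file reading


def _open_text(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _read_record_files(paths: Sequence[str], colmap: Mapping[str, str],
                       delimiter: str, mandatory: Sequence[str]) -> pd.DataFrame:
    frames = []
    for path in paths:
        with _open_text(path) as fh:
            df = pd.read_csv(fh, sep=delimiter, dtype=str, engine="python")
        for key in mandatory:
            if colmap[key] not in df.columns:
                raise IngestError(f"file {path!r} lacks mandatory column {colmap[key]!r}")
        keep = {k: colmap[k] for k in colmap if colmap[k] in df.columns}
        frames.append(df[list(keep.values())].rename(columns={v: k for k, v in keep.items()}))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _find_files(source: str | Sequence[str], prefix: str) -> list[str]:
    if isinstance(source, (list, tuple)):
        return [p for p in source if os.path.basename(p).lower().startswith(prefix)]
    pattern = os.path.join(source, "*")
    return sorted(p for p in glob.glob(pattern)
                  if os.path.basename(p).lower().startswith(prefix))


def read_quarterly_files(source: str | Sequence[str],
                         dialect: DialectConfig | None = None,
                         log: IngestLog | None = None) -> list[SafetyReport]:
    """Read a directory (or explicit list) of quarterly record files.

    Files are matched by basename prefix (``demo``/``drug``/``reac``/
    ``indi``/``ther``, case-insensitive, ``.gz`` accepted). One
    :class:`SafetyReport` is produced per (case id, version) present in
    the DEMO records; drug, reaction, indication and therapy rows are
    joined onto it. Rows that fail to parse are counted, not fatal.
    """
    dialect = dialect or DialectConfig()
    log = log if log is not None else IngestLog()

    groups = {}
    for prefix in ("demo", "drug", "reac", "indi", "ther"):
        groups[prefix] = _find_files(source, prefix)
    if not groups["demo"]:
        raise IngestError(f"no DEMO files found under {source!r}")
    log.files_read += sum(len(v) for v in groups.values())

    demo = _read_record_files(groups["demo"], dialect.demo, dialect.delimiter,
                              mandatory=("case_id", "version"))
    drug = _read_record_files(groups["drug"], dialect.drug, dialect.delimiter,
                              mandatory=("case_id", "name")) if groups["drug"] else pd.DataFrame()
    reac = _read_record_files(groups["reac"], dialect.reac, dialect.delimiter,
                              mandatory=("case_id", "term")) if groups["reac"] else pd.DataFrame()
    indi = _read_record_files(groups["indi"], dialect.indi, dialect.delimiter,
                              mandatory=("case_id", "term")) if groups["indi"] else pd.DataFrame()
    ther = _read_record_files(groups["ther"], dialect.ther, dialect.delimiter,
                              mandatory=("case_id", "start")) if groups["ther"] else pd.DataFrame()

    def _key_frame(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return df
        df = df.copy()
        df["case_id"] = df["case_id"].astype(str).str.strip()
        if "version" in df.columns:
            df["case_ver"] = pd.to_numeric(df["version"], errors="coerce").fillna(1).astype(int)
        else:
            df["case_ver"] = -1  # joined onto every version
        return df

    demo = _key_frame(demo)
    drug = _key_frame(drug)
    reac = _key_frame(reac)
    indi = _key_frame(indi)
    ther = _key_frame(ther)

    # therapy start joined onto drug rows by (case, version, drug sequence)
    if not drug.empty and not ther.empty and "seq" in drug.columns and "seq" in ther.columns:
        ther_small = ther[["case_id", "case_ver", "seq", "start"]]
        drug = drug.merge(ther_small, on=["case_id", "case_ver", "seq"], how="left")
    elif not drug.empty:
        drug["start"] = None

    def _group(df: pd.DataFrame) -> dict:
        if df.empty:
            return {}
        out: dict[tuple, list] = {}
        for row in df.itertuples(index=False):
            out.setdefault((row.case_id, row.case_ver), []).append(row)
        return out

    drug_by_case = _group(drug)
    reac_by_case = _group(reac)
    indi_by_case = _group(indi)

    def _rows_for(table: dict, case_id: str, ver: int) -> list:
        return table.get((case_id, ver), []) + table.get((case_id, -1), [])

    reports: list[SafetyReport] = []
    for row in demo.itertuples(index=False):
        case_id, ver = row.case_id, row.case_ver
        if not case_id:
            log.rows_skipped += 1
            continue
        age = normalize_age(getattr(row, "age", None), getattr(row, "age_unit", None))
        report = SafetyReport(
            case_id=case_id,
            version=ver,
            event_date=normalize_date(getattr(row, "event_date", None)),
            age=age,
            sex=_normalize_sex(getattr(row, "sex", None)),
            country=(str(row.country).strip() or None)
            if getattr(row, "country", None) is not None and not pd.isna(row.country) else None,
            reporter=_normalize_reporter(getattr(row, "reporter", None)),
        )
        for d in _rows_for(drug_by_case, case_id, ver):
            name = str(d.name).strip() if d.name is not None and not pd.isna(d.name) else ""
            if not name:
                log.rows_skipped += 1
                continue
            role = str(getattr(d, "role", "PS")).strip().upper()
            if role not in ROLE_CODES:
                role = "C"
            ai = getattr(d, "active_ingredient", None)
            ai = str(ai).strip() if ai is not None and not pd.isna(ai) else None
            report.drugs.append(DrugEntry(
                name_raw=name, active_ingredient=ai or None, role=role,
                therapy_start=normalize_date(getattr(d, "start", None)),
            ))
        for r in _rows_for(reac_by_case, case_id, ver):
            if r.term is not None and not pd.isna(r.term) and str(r.term).strip():
                report.events.append(str(r.term).strip())
        for i in _rows_for(indi_by_case, case_id, ver):
            if i.term is not None and not pd.isna(i.term) and str(i.term).strip():
                report.indications.append(str(i.term).strip())
        reports.append(report)
        log.reports_in += 1
    return reports


# ---------------------------------------------------------------------------
# version retention and deduplication


def retain_latest_version(reports: Sequence[SafetyReport],
                          log: IngestLog | None = None) -> list[SafetyReport]:
    """Keep, per case id, only the report with the highest version.

    Follow-up reports supersede earlier versions. Two rows with the same
    (case id, version) are a conflict: the first encountered wins and the
    conflict is counted. Output order follows first appearance of each
    case.
    """
    log = log if log is not None else IngestLog()
    best: dict[str, SafetyReport] = {}
    order: list[str] = []
    dropped = 0
    for rep in reports:
        prev = best.get(rep.case_id)
        if prev is None:
            best[rep.case_id] = rep
            order.append(rep.case_id)
        elif rep.version > prev.version:
            best[rep.case_id] = rep
            dropped += 1
        else:
            if rep.version == prev.version:
                log.version_conflicts += 1
                logger.warning("conflicting duplicate of case %s version %s; keeping first",
                               rep.case_id, rep.version)
            dropped += 1
    log.versions_dropped += dropped
    return [best[cid] for cid in order]


def dedup_by_key_variables(reports: Sequence[SafetyReport],
                           log: IngestLog | None = None) -> list[SafetyReport]:
    """Collapse reports sharing the full key-variable tuple to one.

    The key is (age, sex, country, drug-name set, event set, event date);
    absent values match absent values. The first report encountered with
    a given key is retained.
    """
    log = log if log is not None else IngestLog()
    seen: set[tuple] = set()
    out: list[SafetyReport] = []
    for rep in reports:
        key = rep.dedup_key()
        if key in seen:
            log.key_duplicates_dropped += 1
            continue
        seen.add(key)
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# aggregated counts


def read_aggregated_counts(path: str) -> list[AggregatedCounts]:
    """Read a CSV of (drug, n_event, n_total) aggregated counts."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh)
    if df.empty:
        return []
    for col in ("drug", "n_event", "n_total"):
        if col not in df.columns:
            raise IngestError(f"aggregated counts file {path!r} lacks column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(AggregatedCounts(
            drug=str(row.drug).strip().lower(),
            n_event=int(row.n_event),
            n_total=int(row.n_total),
        ))
    return out


def write_aggregated_counts(counts: Iterable[AggregatedCounts], path: str) -> None:
    pd.DataFrame(
        [(c.drug, c.n_event, c.n_total) for c in counts],
        columns=["drug", "n_event", "n_total"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quarterly-file writing (round-trip partner of read_quarterly_files)


def write_quarterly_files(reports: Sequence[SafetyReport], outdir: str,
                          dialect: DialectConfig | None = None,
                          compress: bool = False) -> dict[str, str]:
    """Write reports as one set of $-delimited DEMO/DRUG/REAC/INDI/THER files."""
    dialect = dialect or DialectConfig()
    os.makedirs(outdir, exist_ok=True)
    demo_rows, drug_rows, reac_rows, indi_rows, ther_rows = [], [], [], [], []
    for rep in reports:
        demo_rows.append({
            dialect.demo["case_id"]: rep.case_id,
            dialect.demo["version"]: rep.version,
            dialect.demo["event_date"]: rep.event_date or "",
            dialect.demo["age"]: "" if rep.age is None else f"{rep.age:g}",
            dialect.demo["age_unit"]: "" if rep.age is None else "YR",
            dialect.demo["sex"]: rep.sex or "",
            dialect.demo["country"]: rep.country or "",
            dialect.demo["reporter"]: {"health-professional": "MD", "consumer": "CN"}.get(
                rep.reporter or "", ""),
        })
        for seq, d in enumerate(rep.drugs, start=1):
            drug_rows.append({
                dialect.drug["case_id"]: rep.case_id,
                dialect.drug["version"]: rep.version,
                dialect.drug["seq"]: seq,
                dialect.drug["role"]: d.role,
                dialect.drug["name"]: d.name_raw,
                dialect.drug["active_ingredient"]: d.active_ingredient or "",
            })
            if d.therapy_start:
                ther_rows.append({
                    dialect.ther["case_id"]: rep.case_id,
                    dialect.ther["version"]: rep.version,
                    dialect.ther["seq"]: seq,
                    dialect.ther["start"]: d.therapy_start,
                })
        for term in rep.events:
            reac_rows.append({
                dialect.reac["case_id"]: rep.case_id,
                dialect.reac["version"]: rep.version,
                dialect.reac["term"]: term,
            })
        for term in rep.indications:
            indi_rows.append({
                dialect.indi["case_id"]: rep.case_id,
                dialect.indi["version"]: rep.version,
                dialect.indi["term"]: term,
            })

    suffix = ".txt.gz" if compress else ".txt"
    paths = {}
    for name, rows, colmap in (
        ("demo", demo_rows, dialect.demo), ("drug", drug_rows, dialect.drug),
        ("reac", reac_rows, dialect.reac), ("indi", indi_rows, dialect.indi),
        ("ther", ther_rows, dialect.ther),
    ):
        path = os.path.join(outdir, name + suffix)
        columns = list(colmap.values())
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(path, sep=dialect.delimiter, index=False,
                  compression="gzip" if compress else None)
        paths[name] = path
    return paths
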