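"""Cohort construction: drug mapping, case flagging, exclusions, designs.

Raw drug strings on spontaneous reports are messy ("ENBREL", "methotrexate
sodium", brand names, salts). A :class:`DrugDictionary` maps them to the 36
disease-modifying antirheumatic drugs (DMARDs) of interest and their seven
pharmacological classes. Pulmonary-fibrosis cases are flagged from MedDRA
preferred terms, reports co-listing known pro-fibrotic or antifibrotic
drugs are excluded, and the remaining reports are assembled into an
:class:`AnalysisCohort` under one of two comparator designs:

* ``full_database_wide`` — every report is kept; the comparator for each
  drug is the rest of the whole database.
* ``active_comparator_restricted`` — only reports with a DMARD as primary
  suspect and/or an autoimmune-disorder indication are kept, so cases and
  comparators share the indication.

Exposure to a drug always means "listed as the primary suspect".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SafetyReport

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "conventional DMARDs",
    "TNF-α-targeted inhibitors",
    "B-cell inhibitors",
    "T-cell inhibitors",
    "interleukin inhibitors",
    "JAK inhibitors",
    "PDE4-targeted inhibitor",
)

AGE_GROUPS = ("<=45", "45-65", ">65")

#: country -> coarse region roll-up used as a regression covariate
REGION_MAP = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "GB": "Europe", "DE": "Europe", "FR": "Europe", "IT": "Europe",
    "ES": "Europe", "SE": "Europe", "DK": "Europe", "NL": "Europe",
    "BR": "South America", "AR": "South America",
    "CN": "Asia", "JP": "Asia", "KR": "Asia", "IN": "Asia",
    "AU": "Oceania", "NZ": "Oceania",
}

IMPUTATION_METHODS = ("none", "mode_hotdeck", "iterative_model")


class DictionaryError(ValueError):
    """Invalid drug dictionary (missing class, overlapping synonyms...)."""


def _normalize_name(name: str) -> str:
    """Lower-case, strip punctuation, collapse whitespace."""
    return re.sub(r"[^a-z0-9]+", " ", name.lower()).strip()


def _data_path(name: str):
    return resources.files("fibrovig.data").joinpath(name)


@dataclass
class DrugDictionary:
    """Generic-name dictionary: synonyms/brands and class labels.

    ``entries`` maps each generic to its synonym set (the generic name
    itself is always included); ``class_map`` assigns each generic to one
    of the seven DMARD classes. Normalised synonym strings must be
    disjoint across generics — an ambiguous dictionary is rejected at
    load time rather than at match time.
    """

    entries: dict[str, set[str]]
    class_map: dict[str, str]
    _index: dict[str, str] = field(default_factory=dict, repr=False)
    _match_cache: dict[tuple, str | None] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        for generic, synonyms in self.entries.items():
            if generic not in self.class_map:
                raise DictionaryError(f"generic {generic!r} has no class label")
            if self.class_map[generic] not in CLASS_LABELS:
                raise DictionaryError(
                    f"unknown class {self.class_map[generic]!r} for {generic!r}")
            for syn in set(synonyms) | {generic}:
                key = _normalize_name(syn)
                if not key:
                    continue
                if key in index and index[key] != generic:
                    raise DictionaryError(
                        f"synonym {syn!r} is claimed by both {index[key]!r} and {generic!r}")
                index[key] = generic
        self._index = index

    @classmethod
    def from_csv(cls, path=None) -> "DrugDictionary":
        """Load from CSV with columns generic, class, synonyms ('|'-separated)."""
        source = path if path is not None else _data_path("dmard_dictionary.csv")
        df = pd.read_csv(source).rename(columns={"class": "class_label"})
        entries, class_map = {}, {}
        for row in df.itertuples(index=False):
            generic = str(row.generic).strip().lower()
            syns = set()
            raw = getattr(row, "synonyms", None)
            if raw is not None and not pd.isna(raw):
                syns = {s.strip() for s in str(raw).split("|") if s.strip()}
            entries[generic] = syns
            class_map[generic] = str(row.class_label).strip()
        return cls(entries=entries, class_map=class_map)

    @property
    def generics(self) -> list[str]:
        return sorted(self.entries)

    def match_name(self, name_raw: str | None,
                   active_ingredient: str | None = None) -> str | None:
        """Map a raw drug string (or its stated ingredient) to a generic.

        Exact match on the normalised string is tried first on both
        fields; failing that, a whole-word prefix match absorbs salt and
        ester suffixes ("methotrexate sodium" -> methotrexate).
        """
        key = (name_raw, active_ingredient)
        try:
            return self._match_cache[key]
        except KeyError:
            result = self._match_uncached(name_raw, active_ingredient)
            self._match_cache[key] = result
            return result

    def _match_uncached(self, name_raw: str | None,
                        active_ingredient: str | None = None) -> str | None:
        for candidate in (name_raw, active_ingredient):
            if not candidate:
                continue
            key = _normalize_name(candidate)
            if key in self._index:
                return self._index[key]
        for candidate in (name_raw, active_ingredient):
            if not candidate:
                continue
            tokens = _normalize_name(candidate).split()
            for cut in range(len(tokens) - 1, 0, -1):
                prefix = " ".join(tokens[:cut])
                if prefix in self._index:
                    return self._index[prefix]
        return None


@dataclass
class TermLists:
    """Event and exclusion term lists.

    ``pf_terms`` holds the two pulmonary-fibrosis preferred terms;
    ``autoimmune_pts`` the preferred terms taken to indicate an autoimmune
    indication (the packaged default is a synthetic stand-in — MedDRA is
    licensed and cannot ship here); ``excluded_codrugs`` maps each
    excluded co-medication (bleomycin and the antifibrotics nintedanib /
    pirfenidone) to its synonym set.
    """

    pf_terms: frozenset[str]
    autoimmune_pts: frozenset[str]
    excluded_codrugs: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(self.pf_terms) != 2:
            raise ValueError("pf_terms must hold exactly the two pulmonary-fibrosis PTs")

    @classmethod
    def default(cls, autoimmune_path=None) -> "TermLists":
        pf = frozenset(
            line.strip().lower()
            for line in _data_path("pf_terms.txt").read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#"))
        source = autoimmune_path if autoimmune_path is not None \
            else _data_path("autoimmune_pts_synthetic.txt")
        if hasattr(source, "read_text"):
            text = source.read_text(encoding="utf-8")
        else:
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        auto = frozenset(line.strip().lower() for line in text.splitlines()
                         if line.strip() and not line.startswith("#"))
        excluded = {
            "bleomycin": {"bleomycin sulfate", "Blenoxane"},
            "nintedanib": {"Ofev", "Vargatef", "nintedanib esylate"},
            "pirfenidone": {"Esbriet", "Pirespa"},
        }
        return cls(pf_terms=pf, autoimmune_pts=auto, excluded_codrugs=excluded)

    def is_pf_term(self, term: str) -> bool:
        return term.strip().lower() in self.pf_terms

    def is_autoimmune_term(self, term: str) -> bool:
        return term.strip().lower() in self.autoimmune_pts

    def matches_excluded_codrug(self, name_raw: str) -> bool:
        key = _normalize_name(name_raw)
        for generic, syns in self.excluded_codrugs.items():
            names = {_normalize_name(s) for s in syns} | {_normalize_name(generic)}
            if key in names:
                return True
            tokens = key.split()
            for cut in range(len(tokens), 0, -1):
                if " ".join(tokens[:cut]) in names:
                    return True
        return False


# ---------------------------------------------------------------------------
# per-operation annotators (thin wrappers used by build_cohort and tests)


def map_drug_names(reports: Sequence[SafetyReport],
                   dictionary: DrugDictionary) -> list[list[str | None]]:
    """Per report, per drug entry: the matched generic name or None."""
    return [[dictionary.match_name(d.name_raw, d.active_ingredient) for d in rep.drugs]
            for rep in reports]


def flag_pf_cases(reports: Sequence[SafetyReport], terms: TermLists) -> list[bool]:
    """True where any event PT equals a pulmonary-fibrosis term."""
    return [any(terms.is_pf_term(e) for e in rep.events) for rep in reports]


def apply_exclusions(reports: Sequence[SafetyReport], terms: TermLists,
                     counts: dict | None = None) -> list[SafetyReport]:
    """Drop reports listing bleomycin/nintedanib/pirfenidone in any role.

    The filter is symmetric: it applies to prospective cases and
    comparators alike, so the exclusion cannot bias the odds ratios.
    """
    kept, removed = [], 0
    for rep in reports:
        if any(terms.matches_excluded_codrug(d.name_raw)
               or (d.active_ingredient and terms.matches_excluded_codrug(d.active_ingredient))
               for d in rep.drugs):
            removed += 1
        else:
            kept.append(rep)
    if counts is not None:
        counts["excluded_codrug_reports"] = removed
    logger.info("exclusion filter removed %d reports", removed)
    return kept


def age_group_of(age: float | None) -> str | None:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return None
    if age <= 45:
        return "<=45"
    if age <= 65:
        return "45-65"
    return ">65"


@dataclass
class AnalysisCohort:
    """Annotated report set under one comparator design.

    ``reports`` has one row per report: demographics, ``is_pf`` flag,
    autoimmune-indication flag and calendar year. ``exposures`` has one
    row per (report, matched primary-suspect DMARD): generic name, class
    label and the therapy start date, the unit of counting in per-drug
    tables (a report suspected of two distinct DMARDs counts once for
    each drug).
    """

    design: str
    reports: pd.DataFrame
    exposures: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_pf(self) -> int:
        return int(self.reports["is_pf"].sum())

    def class_exposures(self, class_label: str) -> pd.DataFrame:
        return self.exposures[self.exposures["class_label"] == class_label]


def build_cohort(reports: Sequence[SafetyReport], design: str,
                 dictionary: DrugDictionary, terms: TermLists) -> AnalysisCohort:
    """Annotate reports and restrict them according to the chosen design.

    Expects version retention, key-variable deduplication and the
    co-drug exclusions to have been applied already.
    """
    if design not in ("full_database_wide", "active_comparator_restricted"):
        raise ValueError(f"unknown design {design!r}")

    rows = []
    expo_rows = []
    for rep in reports:
        is_pf = any(terms.is_pf_term(e) for e in rep.events)
        has_auto = any(terms.is_autoimmune_term(t) for t in rep.indications)
        matched = []
        for d in rep.drugs:
            if d.role != "PS":
                continue
            generic = dictionary.match_name(d.name_raw, d.active_ingredient)
            if generic is not None:
                matched.append((generic, d.therapy_start))
        date = rep.event_date
        year = int(date[:4]) if date else None
        rows.append((rep.case_id, rep.age, age_group_of(rep.age), rep.sex, rep.country,
                     rep.reporter, date, year, is_pf, has_auto, len(matched) > 0))
        seen = set()
        for generic, start in matched:
            if generic in seen:  # same drug listed twice counts once
                continue
            seen.add(generic)
            expo_rows.append((rep.case_id, generic, dictionary.class_map[generic],
                              start, is_pf))

    reports_df = pd.DataFrame(rows, columns=[
        "case_id", "age", "age_group", "sex", "country", "reporter",
        "event_date", "year", "is_pf", "has_autoimmune_indication", "dmard_exposed",
    ])
    exposures_df = pd.DataFrame(expo_rows, columns=[
        "case_id", "generic", "class_label", "therapy_start", "is_pf",
    ])

    if design == "active_comparator_restricted" and not reports_df.empty:
        keep = reports_df["dmard_exposed"] | reports_df["has_autoimmune_indication"]
        kept_ids = set(reports_df.loc[keep, "case_id"])
        reports_df = reports_df[keep].reset_index(drop=True)
        if not exposures_df.empty:
            exposures_df = exposures_df[
                exposures_df["case_id"].isin(kept_ids)].reset_index(drop=True)

    reports_df["region"] = reports_df["country"].map(REGION_MAP).where(
        reports_df["country"].notna(), None)
    reports_df.loc[reports_df["country"].notna() & reports_df["region"].isna(),
                   "region"] = "Other"
    return AnalysisCohort(design=design, reports=reports_df, exposures=exposures_df)


# ---------------------------------------------------------------------------
# missing-covariate imputation (pluggable stage)


def impute_missing(cohort: AnalysisCohort, method: str = "none",
                   seed: int | None = 0) -> AnalysisCohort:
    """Fill missing age group / sex / country on the cohort's report table.

    ``mode_hotdeck`` draws each missing value from the column's empirical
    observed distribution; ``iterative_model`` runs a round-robin
    random-forest classifier over the three fields (a pluggable stand-in
    for heavier model-based imputation). Per-field ``*_imputed`` flags are
    retained. With ``none`` the table is returned unchanged and
    complete-case handling is left to the regression stage.
    """
    if method not in IMPUTATION_METHODS:
        raise ValueError(f"unknown imputation method {method!r}; "
                         f"expected one of {IMPUTATION_METHODS}")
    df = cohort.reports.copy()
    fields = ["age_group", "sex", "country"]
    for col in fields:
        df[f"{col}_imputed"] = df[col].isna()
    if method == "none" or df.empty:
        return AnalysisCohort(cohort.design, df, cohort.exposures)

    rng = np.random.default_rng(seed)
    if method == "mode_hotdeck":
        for col in fields:
            observed = df[col].dropna()
            missing = df[col].isna()
            if observed.empty or not missing.any():
                continue
            probs = observed.value_counts(normalize=True)
            draws = rng.choice(probs.index.to_numpy(), size=int(missing.sum()),
                               p=probs.to_numpy())
            df.loc[missing, col] = draws
        df["region"] = df["country"].map(REGION_MAP).fillna("Other")
        return AnalysisCohort(cohort.design, df, cohort.exposures)

    # iterative_model: round-robin random-forest classification
    from sklearn.ensemble import RandomForestClassifier

    work = df[fields].copy()
    for col in fields:  # initial fill: column mode
        observed = work[col].dropna()
        if observed.empty:
            continue
        work[col] = work[col].fillna(observed.mode().iloc[0])
    extra = pd.DataFrame({
        "is_pf": df["is_pf"].astype(int),
        "year": pd.to_numeric(df["year"], errors="coerce").fillna(0),
    })
    for _ in range(3):
        for col in fields:
            missing = df[col].isna()
            if not missing.any() or df[col].dropna().empty:
                continue
            others = [c for c in fields if c != col]
            X = pd.get_dummies(work[others], dummy_na=False).join(extra)
            clf = RandomForestClassifier(
                n_estimators=50, random_state=int(rng.integers(2**31)), n_jobs=1)
            clf.fit(X[~missing.to_numpy()], df.loc[~missing, col])
            work.loc[missing, col] = clf.predict(X[missing.to_numpy()])
    for col in fields:
        df.loc[df[col].isna(), col] = work.loc[df[col].isna(), col]
    df["region"] = df["country"].map(REGION_MAP).fillna("Other")
    return AnalysisCohort(cohort.design, df, cohort.exposures)
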