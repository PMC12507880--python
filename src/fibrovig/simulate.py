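"""Synthetic individual-case-safety-report generator with known ground truth.

Every downstream stage (ingestion, cohort building, disproportionality,
risk-factor regression, time-to-onset) is exercised against scenarios
whose true parameters are known, so estimates can be checked by parameter
recovery instead of by eye.

Event assignment is *logistic*: for a report with primary-suspect drug
``g``, age group ``j`` and sex ``s``,

    logit P(target event) = logit(p0) + ln ROR_g + ln AGE_j + ln SEX_{class(g),s}

where ``p0`` is the background target-event reporting rate. Because the
linear predictor is on the log-odds scale, the injected multipliers are
odds ratios — exactly the estimand of the reporting odds ratio and of the
case–non-case logistic regression, so recovery is exact in expectation.

Onset delays are log-normal per drug class (strictly positive,
heavy-tailed, medians spanning roughly 100–500 days, the shape seen in
real spontaneous-report onset data). Duplicate reports are emitted through
both real-world mechanisms in equal shares: follow-up versions of the
same case id, and near-identical new case ids sharing all key variables.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, CLASS_LABELS, DrugDictionary
from .io import DrugEntry, SafetyReport, write_quarterly_files, write_aggregated_counts

PF_TERMS = ("Pulmonary fibrosis", "Idiopathic pulmonary fibrosis")
OTHER_EVENTS = ("Nausea", "Headache", "Arthralgia", "Rash",
                "Fatigue", "Pyrexia", "Diarrhoea", "Infection")
AUTOIMMUNE_INDICATIONS = ("Rheumatoid arthritis", "Psoriatic arthritis",
                          "Systemic lupus erythematosus", "Ulcerative colitis",
                          "Psoriasis")
OTHER_INDICATIONS = ("Hypertension", "Type 2 diabetes mellitus", "")
BACKGROUND_DRUGS = ("atorvastatin", "metformin", "lisinopril",
                    "amoxicillin", "omeprazole", "sertraline")
CONCOMITANTS = ("paracetamol", "ibuprofen", "prednisone", "folic acid")
EXCLUDED_CODRUGS = ("bleomycin", "nintedanib", "pirfenidone")
COUNTRIES = ("US", "CA", "GB", "DE", "FR", "JP", "BR", "CN")
COUNTRY_WEIGHTS = (0.30, 0.20, 0.12, 0.08, 0.07, 0.07, 0.08, 0.08)

#: probability a report carries an excluded co-drug (exercises the filter)
P_EXCLUDED_CODRUG = 0.002
#: probability an event date is truncated to month resolution
P_PARTIAL_EVENT_DATE = 0.02
#: probability the raw drug string is a brand synonym rather than the generic
P_BRAND_NAME = 0.3

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


class ScenarioError(ValueError):
    """Invalid scenario configuration; the message names the field."""


@dataclass(frozen=True)
class DrugSpec:
    """One catalogued drug: generic name, class and marginal use probability."""

    name: str
    class_label: str
    use_prob: float


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR spread."""
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2 * _Z75)
    return mu, sigma


#: per-class onset-delay models (log-normal mu/sigma), medians ordered
#: B-cell < conventional < interleukin ≈ PDE4 < T-cell < JAK < TNF-α
DEFAULT_TTO_MODEL: dict[str, tuple[str, tuple[float, float]]] = {
    "B-cell inhibitors": ("lognormal", lognormal_from_median_iqr(113, 54, 397)),
    "conventional DMARDs": ("lognormal", lognormal_from_median_iqr(201, 61, 766)),
    "interleukin inhibitors": ("lognormal", lognormal_from_median_iqr(234, 62, 419)),
    "PDE4-targeted inhibitor": ("lognormal", lognormal_from_median_iqr(234, 204, 271)),
    "T-cell inhibitors": ("lognormal", lognormal_from_median_iqr(336, 103, 1006)),
    "JAK inhibitors": ("lognormal", lognormal_from_median_iqr(353, 81, 973)),
    "TNF-α-targeted inhibitors": ("lognormal", lognormal_from_median_iqr(523, 143, 1185)),
    "__other__": ("lognormal", (math.log(60.0), 1.2)),
}


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic reporting scenario."""

    n_reports: int
    drug_catalog: list[DrugSpec]
    background_event_rate: float = 0.002
    true_ror: dict[str, float] = field(default_factory=dict)
    age_distribution: tuple[float, float, float] = (0.30, 0.45, 0.25)
    age_effect: dict[str, float] = field(
        default_factory=lambda: {"<=45": 1.0, "45-65": 1.0, ">65": 1.0})
    sex_ratio: float = 0.65          # probability female
    sex_effect: dict[str, float] = field(default_factory=dict)  # class -> male OR
    missingness: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "country": 0.0})
    tto_model: dict[str, tuple[str, tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_TTO_MODEL))
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ScenarioError("n_reports must be positive")
        if not (0.0 <= self.background_event_rate <= 1.0):
            raise ScenarioError("background_event_rate must lie in [0, 1]")
        total_use = 0.0
        for spec in self.drug_catalog:
            if not (0.0 <= spec.use_prob <= 1.0):
                raise ScenarioError(f"drug_catalog: use_prob of {spec.name!r} not in [0, 1]")
            if spec.class_label not in CLASS_LABELS:
                raise ScenarioError(f"drug_catalog: unknown class {spec.class_label!r}")
            total_use += spec.use_prob
        if total_use > 1.0 + 1e-9:
            raise ScenarioError("drug_catalog: use probabilities sum beyond 1")
        for name, value in self.true_ror.items():
            if value <= 0:
                raise ScenarioError(f"true_ror: multiplier for {name!r} must be positive")
        if abs(sum(self.age_distribution) - 1.0) > 1e-9:
            raise ScenarioError("age_distribution weights must sum to 1")
        if any(w < 0 for w in self.age_distribution):
            raise ScenarioError("age_distribution weights must be non-negative")
        for grp, value in self.age_effect.items():
            if grp not in AGE_GROUPS:
                raise ScenarioError(f"age_effect: unknown age group {grp!r}")
            if value <= 0:
                raise ScenarioError(f"age_effect: multiplier for {grp!r} must be positive")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ScenarioError("sex_ratio must lie in [0, 1]")
        for label, value in self.sex_effect.items():
            if value <= 0:
                raise ScenarioError(f"sex_effect: multiplier for {label!r} must be positive")
        for fieldname, p in self.missingness.items():
            if fieldname not in ("age", "sex", "country"):
                raise ScenarioError(f"missingness: unknown field {fieldname!r}")
            if not (0.0 <= p < 1.0):
                raise ScenarioError(f"missingness: probability for {fieldname!r} not in [0, 1)")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ScenarioError("duplicate_rate must lie in [0, 1)")
        for label, (family, params) in self.tto_model.items():
            if family != "lognormal":
                raise ScenarioError(f"tto_model: unsupported family {family!r} for {label!r}")
            if params[1] < 0:
                raise ScenarioError(f"tto_model: negative sigma for {label!r}")


@dataclass
class GroundTruth:
    """Scenario-implied truth for parameter-recovery checks.

    ``expected_tables`` holds the exact expected 2×2 cell counts per drug
    (so ``sum(a+b+c+d) == n_reports`` for every drug); ``marginal_ror``
    the odds ratio implied by those expected cells (equal to the injected
    conditional multiplier whenever covariate effects or co-elevated
    drugs do not confound the margin); ``class_median_onset`` the true
    median onset delay per class in days; ``age_or`` / ``sex_or`` the
    injected covariate odds ratios.
    """

    expected_tables: dict[str, dict[str, float]]
    marginal_ror: dict[str, float]
    conditional_ror: dict[str, float]
    class_median_onset: dict[str, float]
    age_or: dict[str, float]
    sex_or: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def default_scenario(n_reports: int = 200_000, seed: int = 0) -> ScenarioConfig:
    """Scenario mirroring the study conditions at reduced scale.

    Drug prevalences are not published for the source databases, so the
    marginal use probabilities below are deliberate round numbers; the
    injected reporting odds multipliers and the demographic effects
    follow the magnitudes reported for DMARD-associated pulmonary
    fibrosis (background reporting rate ≈ 0.2% of reports, age odds
    roughly doubling then tripling across age groups, female-majority
    reporting, class-specific sex effects).
    """
    catalog = [
        DrugSpec("methotrexate", "conventional DMARDs", 0.10),
        DrugSpec("leflunomide", "conventional DMARDs", 0.03),
        DrugSpec("etanercept", "TNF-α-targeted inhibitors", 0.08),
        DrugSpec("adalimumab", "TNF-α-targeted inhibitors", 0.10),
        DrugSpec("rituximab", "B-cell inhibitors", 0.04),
        DrugSpec("tocilizumab", "interleukin inhibitors", 0.03),
        DrugSpec("abatacept", "T-cell inhibitors", 0.02),
        DrugSpec("tofacitinib", "JAK inhibitors", 0.04),
        DrugSpec("apremilast", "PDE4-targeted inhibitor", 0.02),
    ]
    return ScenarioConfig(
        n_reports=n_reports,
        drug_catalog=catalog,
        background_event_rate=0.002,
        true_ror={"methotrexate": 4.4, "leflunomide": 3.3, "etanercept": 1.0,
                  "adalimumab": 0.8, "rituximab": 1.4, "tocilizumab": 1.3,
                  "abatacept": 1.2, "tofacitinib": 0.9, "apremilast": 0.5},
        age_effect={"<=45": 1.0, "45-65": 2.0, ">65": 3.0},
        sex_effect={"conventional DMARDs": 1.35, "TNF-α-targeted inhibitors": 1.25,
                    "B-cell inhibitors": 1.45, "interleukin inhibitors": 0.73,
                    "JAK inhibitors": 1.28},
        missingness={"age": 0.25, "sex": 0.10, "country": 0.08},
        duplicate_rate=0.05,
        seed=seed,
    )


def _logit(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _event_probability(config: ScenarioConfig, drug: str, class_label: str,
                       age_group: str, sex: str) -> float:
    x = _logit(config.background_event_rate)
    x += math.log(config.true_ror.get(drug, 1.0))
    x += math.log(config.age_effect.get(age_group, 1.0))
    if sex == "M":
        x += math.log(config.sex_effect.get(class_label, 1.0))
    return float(_sigmoid(np.array(x)))


def compute_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Exact expected 2×2 cell counts by integrating over the covariate mix."""
    age_w = dict(zip(AGE_GROUPS, config.age_distribution))
    sex_w = {"F": config.sex_ratio, "M": 1.0 - config.sex_ratio}
    catalog = list(config.drug_catalog)
    other_prob = 1.0 - sum(s.use_prob for s in catalog)
    full = catalog + [DrugSpec("__other__", catalog[0].class_label if catalog else
                               CLASS_LABELS[0], other_prob)]

    def mean_event_prob(spec: DrugSpec) -> float:
        label = spec.class_label if spec.name != "__other__" else "__none__"
        return sum(
            age_w[g] * sex_w[s] * _event_probability(config, spec.name, label, g, s)
            for g in AGE_GROUPS for s in ("F", "M"))

    n = config.n_reports
    pbar = {spec.name: mean_event_prob(spec) for spec in full}
    total_pf = sum(n * spec.use_prob * pbar[spec.name] for spec in full)
    tables, marginal = {}, {}
    for spec in catalog:
        a = n * spec.use_prob * pbar[spec.name]
        c = n * spec.use_prob - a
        b = total_pf - a
        d = n - total_pf - c
        tables[spec.name] = {"a": a, "b": b, "c": c, "d": d}
        marginal[spec.name] = (a * d) / (b * c) if b > 0 and c > 0 else math.nan
    medians = {label: math.exp(params[0])
               for label, (family, params) in config.tto_model.items()
               if label != "__other__"}
    return GroundTruth(
        expected_tables=tables,
        marginal_ror=marginal,
        conditional_ror={s.name: config.true_ror.get(s.name, 1.0) for s in catalog},
        class_median_onset=medians,
        age_or=dict(config.age_effect),
        sex_or=dict(config.sex_effect),
    )


WINDOW_START = np.datetime64("2004-01-01")
WINDOW_DAYS = int((np.datetime64("2024-01-01") - WINDOW_START)
                  / np.timedelta64(1, "D")) - 1  # last event day 2023-12-31


def _draw_starts(rng: np.random.Generator, delays: np.ndarray) -> np.ndarray:
    """Therapy-start days such that start + delay lands inside the window.

    A windowed extract only captures reports whose event occurred inside
    the study period, so starts are uniform over the feasible range given
    each delay. Delays longer than the window are capped at its length
    (such cases could not be observed at all).
    """
    capped = np.minimum(delays, WINDOW_DAYS - 1)
    offset = np.floor(rng.random(len(delays)) * (WINDOW_DAYS - capped)).astype(int)
    return WINDOW_START + offset.astype("timedelta64[D]"), capped


def _format_dates(days: np.ndarray) -> np.ndarray:
    return np.char.replace(np.datetime_as_string(days, unit="D"), "-", "")


def generate_reports(config: ScenarioConfig,
                     dictionary: DrugDictionary | None = None
                     ) -> tuple[list[SafetyReport], GroundTruth]:
    """Draw one scenario: a report list plus its ground truth.

    Deterministic for a fixed ``config.seed``. Duplicated reports appear
    either as a version-2 row of the same case id or as a fresh case id
    sharing every key variable, in equal shares.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    truth = compute_ground_truth(config)

    catalog = list(config.drug_catalog)
    names = [s.name for s in catalog] + ["__other__"]
    classes = {s.name: s.class_label for s in catalog}
    probs = np.array([s.use_prob for s in catalog]
                     + [1.0 - sum(s.use_prob for s in catalog)])
    drug_idx = rng.choice(len(names), size=n, p=probs)

    age_group_idx = rng.choice(3, size=n, p=np.asarray(config.age_distribution))
    # integer ages whose derived age group matches the drawn group exactly
    age_low = np.array([18.0, 46.0, 66.0])[age_group_idx]
    age_high = np.array([45.0, 65.0, 90.0])[age_group_idx]
    ages = np.round(age_low + rng.random(n) * (age_high - age_low), 0)
    sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    countries = rng.choice(COUNTRIES, size=n, p=np.asarray(COUNTRY_WEIGHTS))
    reporters = np.where(rng.random(n) < 0.68, "health-professional", "consumer")

    # logistic event assignment
    linpred = np.full(n, _logit(config.background_event_rate))
    log_ror = np.array([math.log(config.true_ror.get(nm, 1.0)) for nm in names])
    linpred += log_ror[drug_idx]
    log_age = np.array([math.log(config.age_effect.get(g, 1.0)) for g in AGE_GROUPS])
    linpred += log_age[age_group_idx]
    log_sex = np.array([math.log(config.sex_effect.get(classes.get(nm, ""), 1.0))
                        for nm in names])
    linpred += np.where(sexes == "M", log_sex[drug_idx], 0.0)
    is_pf = rng.random(n) < _sigmoid(linpred)

    # onset delays per class model
    mus = np.empty(n)
    sigmas = np.empty(n)
    other_model = config.tto_model.get("__other__", DEFAULT_TTO_MODEL["__other__"])
    for i_name, nm in enumerate(names):
        label = classes.get(nm)
        family, params = config.tto_model.get(label, other_model)
        mask = drug_idx == i_name
        mus[mask], sigmas[mask] = params
    pf_delay = np.maximum(1, np.round(rng.lognormal(mus, sigmas))).astype(int)
    other_delay = np.maximum(1, np.round(rng.lognormal(math.log(30.0), 1.0, size=n))).astype(int)
    delays = np.where(is_pf, pf_delay, other_delay)

    starts, delays = _draw_starts(rng, delays)
    events_dates = starts + delays.astype("timedelta64[D]")
    start_strs = _format_dates(starts)
    event_strs = _format_dates(events_dates)
    partial = rng.random(n) < P_PARTIAL_EVENT_DATE

    # raw drug-name realisation: sometimes a brand synonym, sometimes upper case
    synonym_pool: dict[str, list[str]] = {}
    if dictionary is None:
        dictionary = DrugDictionary.from_csv()
    for nm in names[:-1]:
        pool = sorted(dictionary.entries.get(nm, set()))
        synonym_pool[nm] = pool
    use_brand = rng.random(n) < P_BRAND_NAME
    brand_pick = rng.random(n)
    upper = rng.random(n) < 0.5

    miss_age = rng.random(n) < config.missingness.get("age", 0.0)
    miss_sex = rng.random(n) < config.missingness.get("sex", 0.0)
    miss_country = rng.random(n) < config.missingness.get("country", 0.0)

    conco = rng.random(n) < 0.25
    conco_pick = rng.integers(0, len(CONCOMITANTS), size=n)
    excl = rng.random(n) < P_EXCLUDED_CODRUG
    excl_pick = rng.integers(0, len(EXCLUDED_CODRUGS), size=n)
    indi_auto = rng.random(n)
    indi_pick = rng.integers(0, len(AUTOIMMUNE_INDICATIONS), size=n)
    other_indi_pick = rng.integers(0, len(OTHER_INDICATIONS), size=n)
    pf_term_pick = rng.random(n)
    other_event_pick = rng.integers(0, len(OTHER_EVENTS), size=n)
    extra_event = rng.random(n) < 0.3
    bg_drug_pick = rng.integers(0, len(BACKGROUND_DRUGS), size=n)

    # scalar extraction from numpy arrays is slow; hoist to plain lists
    drug_idx = drug_idx.tolist()
    ages = ages.tolist()
    sexes = sexes.tolist()
    countries = countries.tolist()
    reporters = reporters.tolist()
    start_strs = np.asarray(start_strs).tolist()
    event_strs = np.asarray(event_strs).tolist()
    partial = partial.tolist()
    use_brand = use_brand.tolist()
    brand_pick = brand_pick.tolist()
    upper = upper.tolist()
    miss_age = miss_age.tolist()
    miss_sex = miss_sex.tolist()
    miss_country = miss_country.tolist()
    conco = conco.tolist()
    conco_pick = conco_pick.tolist()
    excl = excl.tolist()
    excl_pick = excl_pick.tolist()
    indi_auto = indi_auto.tolist()
    indi_pick = indi_pick.tolist()
    other_indi_pick = other_indi_pick.tolist()
    pf_term_pick = pf_term_pick.tolist()
    other_event_pick = other_event_pick.tolist()
    extra_event = extra_event.tolist()
    bg_drug_pick = bg_drug_pick.tolist()
    is_pf_l = is_pf.tolist()

    reports: list[SafetyReport] = []
    for i in range(n):
        nm = names[drug_idx[i]]
        if nm == "__other__":
            raw = BACKGROUND_DRUGS[bg_drug_pick[i]]
        else:
            pool = synonym_pool[nm]
            if use_brand[i] and pool:
                raw = pool[int(brand_pick[i] * len(pool))]
            else:
                raw = nm
            if upper[i]:
                raw = raw.upper()
        drugs = [DrugEntry(name_raw=raw, active_ingredient=None if use_brand[i] else nm,
                           role="PS", therapy_start=start_strs[i])]
        if conco[i]:
            drugs.append(DrugEntry(name_raw=CONCOMITANTS[conco_pick[i]], role="C"))
        if excl[i]:
            drugs.append(DrugEntry(name_raw=EXCLUDED_CODRUGS[excl_pick[i]], role="C"))

        if is_pf_l[i]:
            events = [PF_TERMS[0] if pf_term_pick[i] < 0.75 else PF_TERMS[1]]
            if extra_event[i]:
                events.append("Dyspnoea")
        else:
            events = [OTHER_EVENTS[other_event_pick[i]]]

        if nm != "__other__":
            indications = [AUTOIMMUNE_INDICATIONS[indi_pick[i]]] if indi_auto[i] < 0.8 else []
        else:
            if indi_auto[i] < 0.05:
                indications = [AUTOIMMUNE_INDICATIONS[indi_pick[i]]]
            else:
                chosen = OTHER_INDICATIONS[other_indi_pick[i]]
                indications = [chosen] if chosen else []

        event_date = event_strs[i][:6] if partial[i] else event_strs[i]
        reports.append(SafetyReport(
            case_id=f"C{i:08d}",
            version=1,
            event_date=event_date,
            age=None if miss_age[i] else float(ages[i]),
            sex=None if miss_sex[i] else str(sexes[i]),
            country=None if miss_country[i] else str(countries[i]),
            reporter=str(reporters[i]),
            drugs=drugs,
            events=events,
            indications=indications,
        ))

    # duplicates: half as follow-up versions, half as near-identical new cases
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        half = n_dup // 2
        for j, i in enumerate(dup_idx):
            orig = reports[i]
            clone = SafetyReport(
                case_id=orig.case_id if j < half else f"D{i:08d}",
                version=orig.version + 1 if j < half else 1,
                event_date=orig.event_date, age=orig.age, sex=orig.sex,
                country=orig.country, reporter=orig.reporter,
                drugs=[DrugEntry(d.name_raw, d.active_ingredient, d.role,
                                 d.therapy_start) for d in orig.drugs],
                events=list(orig.events), indications=list(orig.indications),
            )
            reports.append(clone)
    return reports, truth


def aggregate_counts(reports: Sequence[SafetyReport],
                     dictionary: DrugDictionary) -> pd.DataFrame:
    """Aggregated per-drug counts from deduplicated reports.

    Per generic drug: number of reports with the drug as primary suspect
    and, among them, the number listing a target (pulmonary-fibrosis)
    event — the shape of a VigiAccess-style aggregated extract.
    """
    pf_lower = {t.lower() for t in PF_TERMS}
    totals: dict[str, int] = {}
    events: dict[str, int] = {}
    for rep in reports:
        generics = set()
        for d in rep.drugs:
            if d.role != "PS":
                continue
            g = dictionary.match_name(d.name_raw, d.active_ingredient)
            if g is not None:
                generics.add(g)
        if not generics:
            continue
        is_pf = any(e.strip().lower() in pf_lower for e in rep.events)
        for g in generics:
            totals[g] = totals.get(g, 0) + 1
            if is_pf:
                events[g] = events.get(g, 0) + 1
    rows = [(g, events.get(g, 0), totals[g]) for g in sorted(totals)]
    return pd.DataFrame(rows, columns=["drug", "n_event", "n_total"])


def write_scenario(config: ScenarioConfig, outdir: str,
                   dictionary: DrugDictionary | None = None,
                   compress: bool = False) -> dict[str, str]:
    """Generate a scenario and write quarterly files + ground-truth sidecar."""
    dictionary = dictionary or DrugDictionary.from_csv()
    reports, truth = generate_reports(config, dictionary)
    paths = write_quarterly_files(reports, outdir, compress=compress)
    truth_path = os.path.join(outdir, "ground_truth.json")
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    paths["ground_truth"] = truth_path
    agg = aggregate_counts(reports, dictionary)
    agg_path = os.path.join(outdir, "aggregated_counts.csv")
    agg.to_csv(agg_path, index=False)
    paths["aggregated_counts"] = agg_path
    return paths
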