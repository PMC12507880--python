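"""End-to-end orchestration: ingest → dedup → cohort → analyses → bundle.

A single :class:`RunConfig` drives the whole analysis. In report-level
mode the stages run in order — read quarterly files, retain latest case
versions, drop key-variable duplicates, apply co-drug exclusions, build
the cohort(s), then descriptives, per-drug and per-class
disproportionality under both comparator designs, age/sex risk-factor
regression and time-to-onset comparison. In aggregated mode only the
disproportionality stage applies (no report-level covariates or dates
exist). Every filter logs its in/out counts so the screening flow can be
reconstructed from the run log alone, and all randomness descends from
one root seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import descriptives, disproportionality, risk_factors, time_to_onset
from .cohort import DrugDictionary, TermLists
from .io import IngestLog, read_aggregated_counts, read_quarterly_files

logger = logging.getLogger(__name__)

DESIGNS = ("full_database_wide", "active_comparator_restricted")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: ``input_dir`` (quarterly report files) or
    ``aggregated_csv`` (per-drug counts, which disables the regression
    and time-to-onset stages). ``total_event``/``total_reports`` are the
    database totals required in aggregated mode.
    """

    output_dir: str
    input_dir: str | None = None
    aggregated_csv: str | None = None
    total_event: int | None = None
    total_reports: int | None = None
    dictionary_path: str | None = None
    autoimmune_terms_path: str | None = None
    designs: tuple[str, ...] = DESIGNS
    imputation: str = "none"
    ic025_method: str = "gamma"
    continuity: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_dir is None) == (self.aggregated_csv is None):
            raise ValueError("exactly one of input_dir / aggregated_csv must be set")
        if self.aggregated_csv is not None and (
                self.total_event is None or self.total_reports is None):
            raise ValueError("aggregated mode needs total_event and total_reports")
        for d in self.designs:
            if d not in DESIGNS:
                raise ValueError(f"unknown design {d!r}")


@dataclass
class ReportBundle:
    """Paths of the CSV outputs plus the machine-readable summary."""

    output_dir: str
    tables: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    @property
    def summary_path(self) -> str:
        return os.path.join(self.output_dir, "summary.json")


def _write(df: pd.DataFrame, outdir: str, name: str, tables: dict[str, str]) -> None:
    path = os.path.join(outdir, name + ".csv")
    df.to_csv(path, index=False, na_rep="NA")
    tables[name] = path


def run_pipeline(config: RunConfig) -> ReportBundle:
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("fibrovig")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, log_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, log_path: str) -> ReportBundle:
    dictionary = DrugDictionary.from_csv(config.dictionary_path)
    terms = TermLists.default(config.autoimmune_terms_path)
    bundle = ReportBundle(output_dir=config.output_dir)
    flow: list[dict] = []
    signal_sets: dict[str, list[str]] = {}

    if config.aggregated_csv is not None:
        try:
            counts = read_aggregated_counts(config.aggregated_csv)
        except Exception as exc:
            raise StageError(f"stage ingest failed: {exc}") from exc
        flow.append({"stage": "ingest_aggregated", "in": len(counts), "out": len(counts)})
        table = disproportionality.aggregate_signal_table(
            counts, config.total_event, config.total_reports, dictionary)
        _write(table, config.output_dir, "signals_aggregated", bundle.tables)
        signal_sets["aggregated"] = sorted(disproportionality.signal_set(table))
    else:
        ingest_log = IngestLog()
        try:
            reports = read_quarterly_files(config.input_dir, log=ingest_log)
        except Exception as exc:
            raise StageError(f"stage ingest failed: {exc}") from exc
        flow.append({"stage": "ingest", "in": ingest_log.reports_in,
                     "out": len(reports)})
        n0 = len(reports)
        reports = _dedup(reports, ingest_log, flow)
        n_dedup = len(reports)
        counts: dict = {}
        reports = cohort_mod.apply_exclusions(reports, terms, counts)
        flow.append({"stage": "exclusions", "in": n_dedup, "out": len(reports),
                     "excluded_codrug_reports": counts["excluded_codrug_reports"]})
        logger.info("screening flow: raw=%d deduplicated=%d analysable=%d",
                    n0, n_after_dedup(flow), len(reports))

        for design in config.designs:
            try:
                cohort = cohort_mod.build_cohort(reports, design, dictionary, terms)
            except Exception as exc:
                raise StageError(f"stage cohort ({design}) failed: {exc}") from exc
            flow.append({"stage": f"cohort_{design}", "in": len(reports),
                         "out": cohort.n_reports, "pf_cases": cohort.n_pf})
            if config.imputation != "none":
                cohort = cohort_mod.impute_missing(
                    cohort, config.imputation,
                    seed=int(np.random.default_rng(config.seed).integers(2**31)))
            short = "full" if design == "full_database_wide" else "restricted"
            table = disproportionality.drug_signal_table(
                cohort, dictionary, continuity=config.continuity,
                ic025_method=config.ic025_method)
            _write(table, config.output_dir, f"signals_{short}", bundle.tables)
            signal_sets[short] = sorted(disproportionality.signal_set(table))
            _write(disproportionality.class_signal_table(cohort, dictionary),
                   config.output_dir, f"signals_by_class_{short}", bundle.tables)

            if design == "active_comparator_restricted":
                _write(descriptives.summarize_cases(cohort), config.output_dir,
                       "case_characteristics", bundle.tables)
                _write(descriptives.class_shares(cohort), config.output_dir,
                       "class_shares", bundle.tables)
                _write(descriptives.annual_trend(cohort), config.output_dir,
                       "annual_trend", bundle.tables)
                labels = sorted(set(dictionary.class_map.values()))
                try:
                    rf = []
                    for label in labels:
                        rf.extend(risk_factors.age_sex_analysis(cohort, label))
                    _write(risk_factors.results_frame(rf), config.output_dir,
                           "risk_factors", bundle.tables)
                except Exception as exc:
                    raise StageError(f"stage risk_factors failed: {exc}") from exc
                try:
                    samples, summary = time_to_onset.class_tto_analysis(cohort, labels)
                    _write(summary, config.output_dir, "tto_summary", bundle.tables)
                    usable = [s for s in samples if len(s.delays_days) >= 2]
                    if len(usable) >= 2:
                        h, dof, p = time_to_onset.kruskal_wallis(usable)
                        _write(time_to_onset.dunn_posthoc(usable), config.output_dir,
                               "tto_dunn", bundle.tables)
                        bundle.summary["tto_kruskal"] = {"H": h, "df": dof, "p": p}
                    _write(time_to_onset.ecdf_curves(samples), config.output_dir,
                           "tto_ecdf", bundle.tables)
                except Exception as exc:
                    raise StageError(f"stage time_to_onset failed: {exc}") from exc

    if len(signal_sets) > 1:
        bundle.summary["signal_intersection"] = disproportionality.intersect_signal_sets(
            *signal_sets.values())
    bundle.summary.update({
        "signal_sets": signal_sets,
        "flow": flow,
        "seed": config.seed,
        "log": log_path,
    })
    with open(bundle.summary_path, "w", encoding="utf-8") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    return bundle


def _dedup(reports, ingest_log: IngestLog, flow: list[dict]):
    from .io import dedup_by_key_variables, retain_latest_version

    n_in = len(reports)
    reports = retain_latest_version(reports, ingest_log)
    flow.append({"stage": "retain_latest_version", "in": n_in, "out": len(reports),
                 "versions_dropped": ingest_log.versions_dropped})
    n_mid = len(reports)
    reports = dedup_by_key_variables(reports, ingest_log)
    flow.append({"stage": "dedup_key_variables", "in": n_mid, "out": len(reports),
                 "key_duplicates_dropped": ingest_log.key_duplicates_dropped})
    assert n_in == len(reports) + ingest_log.versions_dropped \
        + ingest_log.key_duplicates_dropped, "flow conservation violated"
    return reports


def n_after_dedup(flow: list[dict]) -> int:
    for entry in reversed(flow):
        if entry["stage"] == "dedup_key_variables":
            return entry["out"]
    return 0
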