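"""End-to-end orchestration: tables in, rates and descriptor tables out.

``run`` wires the stages together in the canonical order — cohort
construction, duration estimation, drug-era merging, overlap detection,
person-time splitting, rates and descriptors — and returns every
intermediate product so callers can inspect or re-derive any step.
``write_results`` serialises the standard output tables to CSV
deterministically (stable ordering, fixed formats), which is what the
end-to-end reproducibility check compares byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import coprescribing, descriptors, rates
from .cohort import StudyWindow, build_cohort, full_period_practices
from .intervals import DurationConfig, build_intervals, duration_source_counts, merge_same_drug
from .io import Codelists, Tables, patient_attributes


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    window: StudyWindow = StudyWindow()
    duration: DurationConfig = DurationConfig()
    min_overlap_days: int = 1          # sensitivity variants: 14, 28, 365
    ci_level: float = 0.95
    strata: tuple = rates.STRATA
    long_term_gap_days: int = descriptors.DEFAULT_MAX_GAP_DAYS
    #: restrict to practices contributing for the whole window (sensitivity)
    full_period_only: bool = False
    #: summarise overlap length at episode level instead of pairwise events
    episode_level_lengths: bool = False


@dataclasses.dataclass
class Results:
    config: PipelineConfig
    followup: pd.DataFrame
    exclusions: pd.DataFrame
    tally: dict
    attributes: pd.DataFrame
    intervals: pd.DataFrame
    spans: pd.DataFrame
    events: pd.DataFrame
    episodes: pd.DataFrame
    combinations: pd.DataFrame
    contraindicated: pd.DataFrame
    prevalence: pd.DataFrame
    incidence: pd.DataFrame
    incident_context: pd.DataFrame
    table1: pd.DataFrame
    cells: pd.DataFrame
    prior_ids: pd.Series
    summary: dict


def run(tables: Tables, codelists: Codelists, config: PipelineConfig | None = None) -> Results:
    """Run the full co-prescribing analysis on validated tables."""
    config = config or PipelineConfig()
    window = config.window

    patients, practices = tables.patients, tables.practices
    if config.full_period_only:
        keep = set(full_period_practices(practices, window))
        practices = practices[practices["practice_id"].isin(keep)].reset_index(drop=True)
        patients = patients[patients["practice_id"].isin(keep)].reset_index(drop=True)

    followup, exclusions, tally = build_cohort(
        patients, practices, tables.clinical, window)
    attrs = patient_attributes(
        dataclasses.replace(tables, patients=patients, practices=practices))

    intervals = build_intervals(tables.therapy, config.duration)
    spans = merge_same_drug(intervals, config.duration.same_drug_gap_days)

    events = coprescribing.find_events(spans, followup, codelists)
    if config.min_overlap_days > 1:
        events = coprescribing.threshold_filter(events, config.min_overlap_days)
    episodes = coprescribing.build_episodes(events)
    combinations = coprescribing.combination_counts(events)
    contraindicated, n_contra_people = coprescribing.flag_contraindicated(events, codelists)

    cells = rates.split_person_time(followup, attrs)
    prior_ids = coprescribing.prior_coprescription(spans, followup)
    prevalence = rates.prevalence_rates(events, cells, config.strata, config.ci_level)
    incidence = rates.incidence_rates(events, cells, prior_ids, config.strata,
                                      config.ci_level)

    opioid_spans = spans[spans["drug_class"] == "opioid"]
    context = descriptors.incident_context(
        events, tables.therapy, opioid_spans, tables.clinical,
        prior_patient_ids=prior_ids, max_gap_days=config.long_term_gap_days)
    table1 = descriptors.characteristics_table(
        attrs, followup, events["patient_id"].unique())

    length_frame = episodes if config.episode_level_lengths else events
    length_col = "episode_days" if config.episode_level_lengths else "overlap_days"
    lengths = length_frame[length_col]
    n_included = tally["included"]
    ever = events["patient_id"].nunique()
    overall_prev = prevalence.query("year == 'overall' and stratum_type == 'overall'")
    overall_inc = incidence.query("year == 'overall' and stratum_type == 'overall'")
    summary = {
        "n_input": tally["input"],
        "n_included": n_included,
        "n_excluded_before_entry": sum(tally["excluded_before_entry"].values()),
        "n_no_eligible_followup": tally["no_eligible_followup"],
        "person_years": float(cells["days_in_year"].sum() / rates.DAYS_PER_YEAR),
        "n_ever_coprescribed": int(ever),
        "pct_ever_coprescribed": 100.0 * ever / n_included if n_included else 0.0,
        "prevalence_per_1000py": float(overall_prev["rate_per_1000"].iloc[0])
        if len(overall_prev) else float("nan"),
        "incidence_per_1000py": float(overall_inc["rate_per_1000"].iloc[0])
        if len(overall_inc) else float("nan"),
        "n_prior_coprescribers": int(len(prior_ids)),
        "median_length_days": float(np.median(lengths)) if len(lengths) else float("nan"),
        "iqr_length_days": (
            [float(q) for q in np.percentile(lengths, [25, 75])] if len(lengths) else None),
        "n_contraindicated_people": int(n_contra_people),
        "duration_sources": duration_source_counts(intervals),
    }
    if len(context):
        order = context["order"].value_counts(normalize=True) * 100
        summary["pct_antidepressant_first"] = float(order.get("antidepressant_first", 0.0))
        summary["pct_opioid_first"] = float(order.get("opioid_first", 0.0))
        summary["pct_same_day_start"] = float(order.get("same_day", 0.0))
        summary["pct_any_indication"] = float(100.0 * context["any_indication"].mean())

    return Results(config, followup, exclusions, tally, attrs, intervals, spans,
                   events, episodes, combinations, contraindicated, prevalence,
                   incidence, context, table1, cells, prior_ids, summary)


_OUTPUTS = {
    "followup.csv": "followup",
    "exclusions.csv": "exclusions",
    "intervals.csv": "intervals",
    "events.csv": "events",
    "episodes.csv": "episodes",
    "combinations.csv": "combinations",
    "contraindicated.csv": "contraindicated",
    "rates_prevalence.csv": "prevalence",
    "rates_incidence.csv": "incidence",
    "incident_context.csv": "incident_context",
    "table1.csv": "table1",
}


def write_results(results: Results, out_dir) -> None:
    """Write the standard output tables and the run summary, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fname, attr in _OUTPUTS.items():
        df = getattr(results, attr).copy()
        for c in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[c]):
                df[c] = df[c].dt.strftime("%Y-%m-%d")
        df.to_csv(out / fname, index=False, float_format="%.6f")
    with open(out / "summary.json", "w") as fh:
        json.dump(results.summary, fh, indent=2, sort_keys=True, default=str)
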