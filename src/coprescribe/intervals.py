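"""Prescription coverage intervals: duration estimation and drug-era merging.

Primary-care prescription records carry an issue date but no end date, so
coverage must be estimated. The estimator here follows the established
quantity/daily-dose approach for drug-era construction in UK primary-care
records: the covered duration of a script is ``round(quantity / daily_dose)``
days, with a fallback chain for records where the daily dose is missing —
the stated duration if recorded, else the median duration of valid scripts
of the same drug, else a global default — and a hard cap on implausibly long
single scripts. Every decision point is a field of :class:`DurationConfig`
and every estimated duration carries its provenance (``duration_source``).

Intervals of the same drug for one person are then merged into coverage
spans ("drug eras"): overlapping or near-adjacent scripts are unioned, with
no stockpiling — an early refill never pushes coverage beyond the union of
the scripts' own intervals. This is the conservative choice for an
overlap-based outcome, since carrying surplus supply forward would
manufacture spurious co-prescription days.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class DurationConfig:
    """Tunable constants of the duration estimator.

    max_duration_days
        Cap on any single-script duration (default 183 days, roughly a
        six-month supply — longer is treated as a data artefact).
    default_duration_days
        Global fallback when nothing else is available (default 28 days, the
        typical UK repeat-script length).
    fallback_strategy
        ``"drug_median"`` (default) inserts the per-drug median of valid
        computed durations ahead of the global default; ``"global_default"``
        skips it.
    same_drug_gap_days
        Merge tolerance between consecutive same-drug intervals (default 0:
        only overlapping or exactly adjacent scripts join an era).
    implausible_factor
        If set, a quantity/dose result above ``max_duration_days *
        implausible_factor`` is treated as implausible and routed to the
        fallback chain instead of being capped. Off (None) by default:
        computed durations are clamped to ``[1, max_duration_days]``.
    """

    max_duration_days: int = 183
    default_duration_days: int = 28
    fallback_strategy: str = "drug_median"
    same_drug_gap_days: int = 0
    implausible_factor: float | None = None

    def __post_init__(self):
        if not self.max_duration_days >= self.default_duration_days >= 1:
            raise ValueError("require max_duration_days >= default_duration_days >= 1")
        if self.same_drug_gap_days < 0:
            raise ValueError("same_drug_gap_days must be >= 0")
        if self.fallback_strategy not in ("drug_median", "global_default"):
            raise ValueError(f"unknown fallback_strategy {self.fallback_strategy!r}")


def estimate_duration(quantity, daily_dose, stated_duration_days, config: DurationConfig,
                      drug_median=None) -> tuple[int, str]:
    """Estimate one script's covered days with provenance.

    Returns ``(days, source)`` with source one of ``quantity_dose``,
    ``stated``, ``drug_median``, ``default`` or ``capped`` (the last
    whenever the cap bound, regardless of route).
    """
    days, source = None, None
    if daily_dose is not None and not pd.isna(daily_dose) and daily_dose > 0:
        computed = int(round(quantity / daily_dose))
        if config.implausible_factor is None or computed <= (
            config.max_duration_days * config.implausible_factor
        ):
            days, source = max(1, computed), "quantity_dose"
    if days is None and stated_duration_days is not None and not pd.isna(stated_duration_days):
        days, source = max(1, int(stated_duration_days)), "stated"
    if days is None and config.fallback_strategy == "drug_median" and drug_median is not None \
            and not pd.isna(drug_median):
        days, source = max(1, int(drug_median)), "drug_median"
    if days is None:
        days, source = config.default_duration_days, "default"
    if days > config.max_duration_days:
        days, source = config.max_duration_days, "capped"
    return days, source


def drug_medians(therapy: pd.DataFrame, config: DurationConfig) -> pd.Series:
    """Per-drug median of valid quantity/dose durations (clamped to the cap)."""
    ok = therapy["daily_dose"].notna() & (therapy["daily_dose"] > 0)
    t = therapy[ok]
    days = np.clip(
        np.rint(t["quantity"] / t["daily_dose"]).astype(int),
        1, config.max_duration_days,
    )
    med = days.groupby(t["drug_name"]).median()
    return np.rint(med).astype(int)


def build_intervals(therapy: pd.DataFrame, config: DurationConfig | None = None) -> pd.DataFrame:
    """One coverage interval per prescription.

    Returns a frame with patient_id, drug_name, drug_class, start (issue
    date), end (last covered day, inclusive), duration_days and
    duration_source. Per-drug medians for the fallback chain are computed
    from the same table in a first pass.
    """
    config = config or DurationConfig()
    med = drug_medians(therapy, config)

    qty = therapy["quantity"].to_numpy(dtype=float)
    dose = therapy["daily_dose"].to_numpy(dtype=float)
    stated = therapy["stated_duration_days"].to_numpy(dtype=float, na_value=np.nan)
    dmed = therapy["drug_name"].map(med).to_numpy(dtype=float, na_value=np.nan)

    computed = np.rint(np.divide(qty, dose, out=np.full_like(qty, np.nan), where=dose > 0))
    have_qd = ~np.isnan(computed)
    if config.implausible_factor is not None:
        have_qd &= computed <= config.max_duration_days * config.implausible_factor
    computed = np.maximum(computed, 1)

    if config.fallback_strategy != "drug_median":
        dmed = np.full_like(dmed, np.nan)

    days = np.select(
        [have_qd, ~np.isnan(stated), ~np.isnan(dmed)],
        [computed, np.maximum(stated, 1), np.maximum(dmed, 1)],
        default=float(config.default_duration_days),
    )
    source = np.select(
        [have_qd, ~np.isnan(stated), ~np.isnan(dmed)],
        ["quantity_dose", "stated", "drug_median"],
        default="default",
    )
    over = days > config.max_duration_days
    days = np.where(over, config.max_duration_days, days).astype(int)
    source = np.where(over, "capped", source)

    out = therapy[["patient_id", "drug_name", "drug_class"]].copy()
    out["start"] = therapy["issue_date"]
    out["end"] = therapy["issue_date"] + pd.to_timedelta(days - 1, unit="D")
    out["duration_days"] = days
    out["duration_source"] = source
    return out


def duration_source_counts(intervals: pd.DataFrame) -> dict:
    return intervals["duration_source"].value_counts().to_dict()


def _merge_sorted(df: pd.DataFrame, keys: list[str], gap: int) -> pd.DataFrame:
    """Union-merge closed intervals within groups; requires start/end columns.

    Two consecutive intervals join when the uncovered gap between them is at
    most ``gap`` days. Fully vectorised: a new span starts where an
    interval's start exceeds the running maximum end of its group by more
    than ``gap + 1`` days.
    """
    if df.empty:
        return df[keys + ["start", "end"]].copy()
    df = df.sort_values(keys + ["start", "end"], kind="stable").reset_index(drop=True)
    g = df.groupby(keys, sort=False)
    run_end = g["end"].cummax()
    prev_end = run_end.groupby([df[k] for k in keys], sort=False).shift(1)
    new_span = prev_end.isna() | (
        df["start"] > prev_end + pd.Timedelta(days=gap + 1)
    )
    span_id = new_span.cumsum()
    merged = df.groupby(span_id).agg(
        **{k: (k, "first") for k in keys}, start=("start", "min"), end=("end", "max")
    )
    return merged.reset_index(drop=True)


def merge_same_drug(intervals: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge per-(patient, drug) intervals into coverage spans (drug eras).

    Idempotent: merging the result again changes nothing. The covered-day
    set of the output equals the union of the inputs' day sets exactly when
    ``gap == 0``; a positive gap additionally bridges uncovered runs up to
    that length.
    """
    spans = _merge_sorted(
        intervals, ["patient_id", "drug_class", "drug_name"], gap
    )
    spans["span_days"] = (spans["end"] - spans["start"]).dt.days + 1
    return spans
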