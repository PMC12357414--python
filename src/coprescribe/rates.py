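"""Prevalence and incidence of co-prescribing per 1000 person-years.

Follow-up is split into calendar-year person-time cells carrying
time-updated stratum labels (age band attained on 1 January of the cell
year; sex, deprivation quintile and ethnic group are fixed). Rates are
crude:

* **prevalence** — distinct persons with at least one co-prescribed day in
  a (year, stratum) cell, per 1000 person-years of follow-up in that cell;
  the denominator keeps full follow-up (person-time is not truncated at
  events). Period-wide ("overall") rates count a person once per calendar
  year they are prevalent, so the overall rate is the person-year-weighted
  average of the yearly rates.
* **incidence** — first-ever co-prescription events among persons with no
  prior co-prescription (including lookback before study entry), per 1000
  person-years at risk; at-risk time runs from entry to the earlier of the
  first event and exit, and prior co-prescribers are removed from numerator
  and denominator entirely.

Confidence intervals are exact Poisson (gamma-quantile) limits — correct in
small strata and indistinguishable from the normal approximation in large
ones. Person-years are days / 365.25.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import StudyWindow, age_band

DAYS_PER_YEAR = 365.25

STRATA = ("sex", "age_band", "townsend", "ethnic_group")

RATE_COLUMNS = [
    "year", "stratum_type", "stratum", "numerator", "person_years",
    "rate_per_1000", "ci_low", "ci_high",
]


def split_person_time(followup: pd.DataFrame, attributes: pd.DataFrame) -> pd.DataFrame:
    """Per (person, calendar year) follow-up day counts with stratum labels.

    ``attributes`` is the resolved patient frame (``io.patient_attributes``)
    supplying sex, birth_year, townsend and ethnic_group. Day counts are
    closed-interval; their sum over cells equals total follow-up days
    exactly. The age band of a cell is the age attained on 1 January of the
    cell year (``year - birth_year``).
    """
    fu = followup.merge(
        attributes[["patient_id", "sex", "birth_year", "townsend", "ethnic_group"]],
        on="patient_id", how="left", validate="one_to_one",
    )
    rows = []
    for r in fu.itertuples(index=False):
        entry, exit_ = r.entry_date.date(), r.exit_date.date()
        for year in range(entry.year, exit_.year + 1):
            lo = max(entry, dt.date(year, 1, 1))
            hi = min(exit_, dt.date(year, 12, 31))
            rows.append((
                r.patient_id, year, lo, hi, (hi - lo).days + 1, r.sex,
                age_band(year - r.birth_year), r.townsend, r.ethnic_group,
            ))
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "year", "cell_start", "cell_end", "days_in_year",
                 "sex", "age_band", "townsend", "ethnic_group"],
    )
    for c in ("cell_start", "cell_end"):
        out[c] = pd.to_datetime(out[c])
    return out


def rate_ci(count: int, person_years: float, level: float = 0.95):
    """Exact Poisson (gamma-quantile) CI for a rate per 1000 person-years."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if person_years <= 0:
        raise ValueError("person_years must be > 0")
    alpha = 1 - level
    low = 0.0 if count == 0 else stats.gamma.ppf(alpha / 2, a=count)
    high = stats.gamma.ppf(1 - alpha / 2, a=count + 1)
    scale = 1000.0 / person_years
    return low * scale, high * scale


def prevalent_person_years(events: pd.DataFrame) -> pd.DataFrame:
    """Distinct (patient, year) pairs with >= 1 co-prescribed day.

    An event interval contributes every calendar year it touches; any year
    strictly inside the interval is fully covered, and boundary years get at
    least the boundary day.
    """
    if events.empty:
        return pd.DataFrame(columns=["patient_id", "year"])
    rows = []
    for r in events.itertuples(index=False):
        for year in range(r.overlap_start.year, r.overlap_end.year + 1):
            rows.append((r.patient_id, year))
    return pd.DataFrame(rows, columns=["patient_id", "year"]).drop_duplicates(
        ignore_index=True
    )


def _rate_rows(numer: pd.DataFrame, cells: pd.DataFrame, strata, level: float):
    """Assemble the StratumRate table from per-cell numerator pairs.

    ``numer`` holds one row per counted (patient, year) with stratum labels
    already joined; ``cells`` are the person-time cells for the denominator.
    Emits per-year and period-wide rows, overall and per requested stratum.
    Cells with zero person-years in a requested combination simply do not
    appear (there is no one to report on).
    """
    out = []

    def emit(year, stype, svalue, n, py):
        if py <= 0:
            return
        lo, hi = rate_ci(int(n), py, level)
        out.append((year, stype, svalue, int(n), py, 1000.0 * n / py, lo, hi))

    def block(stype, keys):
        denom = cells.groupby(keys, dropna=False)["days_in_year"].sum() / DAYS_PER_YEAR
        num = numer.groupby(keys, dropna=False)["patient_id"].nunique() if len(numer) \
            else pd.Series(dtype=int)
        for key, py in denom.items():
            n = num.get(key, 0)
            if stype == "overall":
                emit(key, "overall", "all", n, py)
            else:
                year, svalue = key
                emit(year, stype, svalue, n, py)
        # period-wide ("overall" year): person counted once per prevalent year
        if stype == "overall":
            emit("overall", "overall", "all", num.sum() if len(num) else 0, denom.sum())
        else:
            year_key = keys[1]
            pys = denom.groupby(level=1).sum()
            ns = num.groupby(level=1).sum() if len(num) else pd.Series(dtype=int)
            for svalue, py in pys.items():
                emit("overall", stype, svalue, ns.get(svalue, 0), py)

    block("overall", ["year"])
    for s in strata:
        block(s, ["year", s])
    return pd.DataFrame(out, columns=RATE_COLUMNS)


def prevalence_rates(events: pd.DataFrame, cells: pd.DataFrame,
                     strata=STRATA, level: float = 0.95) -> pd.DataFrame:
    """Prevalence per 1000 person-years, overall, by year and by stratum."""
    prev = prevalent_person_years(events)
    numer = prev.merge(cells, on=["patient_id", "year"], how="inner")
    return _rate_rows(numer, cells, strata, level)


def incidence_rates(events: pd.DataFrame, cells: pd.DataFrame,
                    prior_patient_ids, strata=STRATA, level: float = 0.95) -> pd.DataFrame:
    """Incidence per 1000 person-years at risk.

    ``prior_patient_ids`` (from
    :func:`coprescribe.coprescribing.prior_coprescription`) are removed from
    numerator and denominator. At-risk person-time is truncated at the first
    event date.
    """
    prior = set(prior_patient_ids)
    cells = cells[~cells["patient_id"].isin(prior)].copy()
    ev = events[~events["patient_id"].isin(prior)]
    if ev.empty:
        first = pd.DataFrame({"patient_id": pd.Series(dtype=object),
                              "first_event_date": pd.Series(dtype="datetime64[ns]")})
    else:
        first = (
            ev.groupby("patient_id", as_index=False)["overlap_start"].min()
            .rename(columns={"overlap_start": "first_event_date"})
        )

    # truncate at-risk time at the first event date: drop cells that start
    # after it, shorten the cell containing it (event day itself is at risk)
    cells = cells.merge(first, on="patient_id", how="left")
    fed = cells["first_event_date"]
    trunc_end = cells["cell_end"].where(fed.isna(), np.minimum(cells["cell_end"], fed))
    cells["days_in_year"] = (trunc_end - cells["cell_start"]).dt.days + 1
    cells["cell_end"] = trunc_end
    cells = cells[cells["days_in_year"] > 0].copy()

    numer = first.assign(year=first["first_event_date"].dt.year).merge(
        cells, on=["patient_id", "year"], how="inner"
    )
    return _rate_rows(numer, cells.drop(columns=["first_event_date"]), strata, level)
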