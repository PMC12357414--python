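"""Brute-force day-enumeration reference for the whole analysis.

This module recomputes every downstream quantity by marking individual
calendar days on a per-person boolean day grid — no interval arithmetic, no
merging, no min/max date algebra beyond per-day comparisons. It exists for
two purposes:

* the synthetic generator derives its planted ground truth with it (from the
  *true* script durations), independently of the pipeline under test;
* the test suite checks the interval-based pipeline against it (from the
  *estimated* durations), where the two must agree exactly.

It is deliberately slow and simple; never use it as the analysis path.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import Counter

import numpy as np
import pandas as pd

from ._dates import anniversary
from .cohort import StudyWindow
from .io import CENSOR_CATEGORIES


@dataclasses.dataclass
class DayEnumerationResult:
    """Per-person and per-year quantities from exhaustive day marking.

    Day sets are frozensets of proleptic-Gregorian ordinals.
    """

    window: StudyWindow
    followup: dict           # pid -> (entry_date, exit_date), included persons only
    excluded_before_entry: dict   # pid -> censor category
    no_eligible_followup: set
    followup_days: dict      # pid -> int
    co_day_sets: dict        # pid -> frozenset[int], non-empty only
    pair_event_counts: Counter   # (opioid, antidepressant) -> maximal-run count
    pair_people: dict        # (opioid, antidepressant) -> set of pids
    prevalent_by_year: dict  # year -> set of pids
    person_days_by_year: dict    # year -> int (denominator days)
    prior_ids: set           # pids with co-coverage before entry
    incident_first_day: dict     # pid -> date of first co-prescribed day
    at_risk_days_by_year: dict   # year -> int, incidence denominator days:
    # follow-up of non-prior persons truncated at the first co-prescribed day

    @property
    def coprescribed_ids(self):
        return set(self.co_day_sets)

    def incident_by_year(self) -> dict:
        out: dict = {}
        for pid, d in self.incident_first_day.items():
            out.setdefault(d.year, set()).add(pid)
        return out


def enumerate_reference(patients: pd.DataFrame, practices: pd.DataFrame,
                        clinical: pd.DataFrame, scripts: pd.DataFrame,
                        window: StudyWindow) -> DayEnumerationResult:
    """Run the day-enumeration reference over one cohort.

    ``scripts`` needs patient_id, drug_name, drug_class, issue_date and
    duration_days columns (true durations for ground truth, estimated ones
    for pipeline validation).
    """
    wstart = window.start.toordinal()
    wend = window.end.toordinal()
    if len(scripts):
        axis_start = min(wstart, scripts["issue_date"].min().date().toordinal())
    else:
        axis_start = wstart
    days = np.arange(axis_start, wend + 1)      # ordinals, one per calendar day
    n = len(days)
    in_window = days >= wstart
    day_years = np.array([dt.date.fromordinal(int(o)).year for o in days])

    prac = practices.set_index("practice_id")
    cens = clinical[clinical["category"].isin(CENSOR_CATEGORIES)]
    cens = cens.sort_values(["event_date", "category"], kind="stable")
    first_censor = {
        pid: (g["event_date"].iloc[0].date(), g["category"].iloc[0])
        for pid, g in cens.groupby("patient_id", sort=False)
    }
    scripts_by = dict(iter(scripts.groupby("patient_id"))) if len(scripts) else {}

    res = DayEnumerationResult(
        window=window, followup={}, excluded_before_entry={},
        no_eligible_followup=set(), followup_days={}, co_day_sets={},
        pair_event_counts=Counter(), pair_people={}, prevalent_by_year={},
        person_days_by_year={}, prior_ids=set(), incident_first_day={},
        at_risk_days_by_year={},
    )

    def add_days(target: dict, m: np.ndarray):
        for y in np.unique(day_years[m]):
            y = int(y)
            target[y] = target.get(y, 0) + int((m & (day_years == y)).sum())

    for row in patients.itertuples(index=False):
        pid = row.patient_id
        p = prac.loc[row.practice_id]
        by = int(row.birth_year)

        # day-wise eligibility predicate
        mask = (
            (days >= anniversary(row.registration_date.date()).toordinal())
            & (days >= anniversary(p["uts_date"].date()).toordinal())
            & (days >= dt.date(by + window.min_age, 1, 1).toordinal())
            & in_window
            & (days <= p["last_collection_date"].date().toordinal())
            & (days <= dt.date(by + window.max_age + 1, 1, 1).toordinal())
        )
        if not pd.isna(row.death_date):
            mask &= days <= row.death_date.date().toordinal()
        if not pd.isna(row.transfer_out_date):
            mask &= days <= row.transfer_out_date.date().toordinal()

        if not mask.any():
            res.no_eligible_followup.add(pid)
            continue
        entry_ix = int(np.argmax(mask))
        censor = first_censor.get(pid)
        if censor is not None:
            cord = censor[0].toordinal()
            if cord < days[entry_ix]:
                res.excluded_before_entry[pid] = censor[1]
                continue
            mask &= days <= cord
        if not mask.any():       # unreachable given censor >= entry, kept for safety
            res.no_eligible_followup.add(pid)
            continue

        entry = dt.date.fromordinal(int(days[np.argmax(mask)]))
        exit_ = dt.date.fromordinal(int(days[n - 1 - np.argmax(mask[::-1])]))
        res.followup[pid] = (entry, exit_)
        res.followup_days[pid] = int(mask.sum())
        add_days(res.person_days_by_year, mask)

        sc = scripts_by.get(pid)
        if sc is None:
            add_days(res.at_risk_days_by_year, mask)
            continue
        drug_masks: dict = {}
        for s in sc.itertuples(index=False):
            o = s.issue_date.date().toordinal()
            lo = max(0, o - axis_start)
            hi = min(n, o - axis_start + int(s.duration_days))
            if hi <= lo:
                continue
            m = drug_masks.setdefault((s.drug_class, s.drug_name), np.zeros(n, dtype=bool))
            m[lo:hi] = True

        op = np.zeros(n, dtype=bool)
        ad = np.zeros(n, dtype=bool)
        for (cls, _), m in drug_masks.items():
            if cls == "opioid":
                op |= m
            else:
                ad |= m

        # prior co-prescription: both classes cover a day before entry
        prior_mask = op & ad & (days < entry.toordinal())
        if prior_mask.any():
            res.prior_ids.add(pid)

        co = mask & op & ad
        if pid not in res.prior_ids:
            risk = mask & (days <= days[np.argmax(co)]) if co.any() else mask
            add_days(res.at_risk_days_by_year, risk)
        if co.any():
            res.co_day_sets[pid] = frozenset(int(d) for d in days[co])
            for y in np.unique(day_years[co]):
                res.prevalent_by_year.setdefault(int(y), set()).add(pid)
            if pid not in res.prior_ids:
                res.incident_first_day[pid] = dt.date.fromordinal(int(days[np.argmax(co)]))
            opioids = [k for k in drug_masks if k[0] == "opioid"]
            antideps = [k for k in drug_masks if k[0] == "antidepressant"]
            for ko in opioids:
                for ka in antideps:
                    pm = mask & drug_masks[ko] & drug_masks[ka]
                    if pm.any():
                        runs = int(pm[0]) + int(np.count_nonzero(pm[1:] & ~pm[:-1]))
                        pair = (ko[1], ka[1])
                        res.pair_event_counts[pair] += runs
                        res.pair_people.setdefault(pair, set()).add(pid)
    return res
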