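"""Study-population construction: entry, exit, exclusion and censoring.

Eligibility follows the standard UK primary-care database design for a
2010–2019 adult cohort. A person enters the study at the latest of:

* one year after registration with their practice,
* one year after the practice's up-to-standard (data quality) date,
* 1 January of the year they turn 18,
* the study window start.

They exit at the earliest of death, leaving the practice, the practice's
last data collection, 1 January of the year they turn 101, or the window
end. To focus on non-cancer pain prescribing, a first record of cancer,
terminal illness, heart failure or opioid misuse excludes the person when it
falls strictly before entry, and censors follow-up at its date otherwise.

Follow-up intervals are closed ``[entry, exit]``; a one-day record
contributes one day. Persons with ``entry > exit`` have no eligible
follow-up and are dropped (tallied separately from exclusions).
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import pandas as pd

from ._dates import anniversary
from .io import CENSOR_CATEGORIES

#: age bands used for stratified rates and descriptive tables
AGE_BANDS = ((18, 34), (35, 44), (45, 54), (55, 64), (65, 74), (75, 84), (85, 100))
AGE_BAND_LABELS = tuple(f"{lo}-{hi}" for lo, hi in AGE_BANDS)

#: tie-break precedence when several exit candidates fall on the same date
EXIT_PRECEDENCE = ("death", "transfer_out", "last_collection", "turned_101", "study_end")

CENSOR_REASONS = {
    "cancer": "censor_cancer",
    "terminal_illness": "censor_terminal",
    "heart_failure": "censor_heart_failure",
    "opioid_misuse": "censor_opioid_misuse",
}


def age_band(age: int) -> str:
    """Band label for an attained age; ages past 100 stay in the top band."""
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if age <= hi:
            return label
    return AGE_BAND_LABELS[-1]


@dataclasses.dataclass(frozen=True)
class StudyWindow:
    start: dt.date = dt.date(2010, 1, 1)
    end: dt.date = dt.date(2019, 12, 31)
    min_age: int = 18
    max_age: int = 100

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("study window start must precede end")


def study_entry(registration_date: dt.date, uts_date: dt.date, birth_year: int,
                window: StudyWindow) -> dt.date:
    """Latest of the four entry candidates."""
    return max(
        anniversary(registration_date),
        anniversary(uts_date),
        dt.date(birth_year + window.min_age, 1, 1),
        window.start,
    )


def study_exit(death_date, transfer_out_date, last_collection_date: dt.date,
               birth_year: int, window: StudyWindow) -> tuple[dt.date, str]:
    """Earliest of the five exit candidates with its reason.

    Ties are broken by the fixed precedence death > transfer_out >
    last_collection > turned_101 > study_end.
    """
    candidates = {
        "death": death_date,
        "transfer_out": transfer_out_date,
        "last_collection": last_collection_date,
        "turned_101": dt.date(birth_year + window.max_age + 1, 1, 1),
        "study_end": window.end,
    }
    best_date, best_reason = None, None
    for reason in EXIT_PRECEDENCE:
        d = candidates[reason]
        if d is None or pd.isna(d):
            continue
        if best_date is None or d < best_date:
            best_date, best_reason = d, reason
    return best_date, best_reason


def apply_exclusion_censoring(entry: dt.date, exit_date: dt.date, exit_reason: str,
                              first_censor):
    """Apply the earliest disqualifying clinical event to one follow-up.

    ``first_censor`` is ``None`` or ``(date, category)`` for the earliest
    event among the censoring categories. Strictly before entry -> the person
    is excluded (returns ``("excluded", category)``). On or after entry and
    no later than exit -> follow-up is censored at the event date (an event
    exactly on the entry date censors at entry, leaving one day of
    follow-up). An event on the exit date itself replaces the administrative
    reason with the censor reason unless the exit was a death.
    """
    if first_censor is None:
        return "included", entry, exit_date, exit_reason
    cdate, category = first_censor
    if cdate < entry:
        return "excluded", None, None, category
    if cdate <= exit_date and not (cdate == exit_date and exit_reason == "death"):
        return "included", entry, cdate, CENSOR_REASONS[category]
    return "included", entry, exit_date, exit_reason


def build_cohort(patients: pd.DataFrame, practices: pd.DataFrame,
                 clinical: pd.DataFrame, window: StudyWindow):
    """Compute follow-up for every patient and the selection tally.

    Returns ``(followup, exclusions, tally)``:

    * ``followup`` — one row per included person: patient_id, entry_date,
      exit_date, exit_reason;
    * ``exclusions`` — patient_id and category for persons with a censoring
      event strictly before entry;
    * ``tally`` — flow-chart counts: input, excluded-before-entry by
      category, no-eligible-follow-up, included, and exit reasons.
    """
    prac = practices.set_index("practice_id")
    cens = clinical[clinical["category"].isin(CENSOR_CATEGORIES)]
    cens = cens.sort_values(["event_date", "category"], kind="stable")
    first_censor = {
        pid: (g["event_date"].iloc[0].date(), g["category"].iloc[0])
        for pid, g in cens.groupby("patient_id", sort=False)
    }

    fu_rows, ex_rows = [], []
    tally = {
        "input": len(patients),
        "excluded_before_entry": {c: 0 for c in CENSOR_CATEGORIES},
        "no_eligible_followup": 0,
        "included": 0,
        "exit_reasons": {},
    }
    for row in patients.itertuples(index=False):
        p = prac.loc[row.practice_id]
        entry = study_entry(row.registration_date.date(), p["uts_date"].date(),
                            int(row.birth_year), window)
        exit_date, reason = study_exit(
            None if pd.isna(row.death_date) else row.death_date.date(),
            None if pd.isna(row.transfer_out_date) else row.transfer_out_date.date(),
            p["last_collection_date"].date(), int(row.birth_year), window,
        )
        if entry > exit_date:
            tally["no_eligible_followup"] += 1
            continue
        status, entry, exit_date, reason = apply_exclusion_censoring(
            entry, exit_date, reason, first_censor.get(row.patient_id)
        )
        if status == "excluded":
            tally["excluded_before_entry"][reason] += 1
            ex_rows.append((row.patient_id, reason))
            continue
        tally["included"] += 1
        tally["exit_reasons"][reason] = tally["exit_reasons"].get(reason, 0) + 1
        fu_rows.append((row.patient_id, entry, exit_date, reason))

    followup = pd.DataFrame(fu_rows, columns=["patient_id", "entry_date", "exit_date", "exit_reason"])
    for c in ("entry_date", "exit_date"):
        followup[c] = pd.to_datetime(followup[c])
    exclusions = pd.DataFrame(ex_rows, columns=["patient_id", "category"])
    return followup, exclusions, tally


def full_period_practices(practices: pd.DataFrame, window: StudyWindow) -> pd.Series:
    """Practice ids contributing for the entire study window.

    A practice contributes throughout when its data are up-to-standard at
    least a year before the window starts and collection continues to the
    window end — the restriction used for the declining-panel sensitivity
    analysis.
    """
    ok = (
        (practices["uts_date"] <= pd.Timestamp(window.start) - pd.DateOffset(years=1))
        & (practices["last_collection_date"] >= pd.Timestamp(window.end))
    )
    return practices.loc[ok, "practice_id"]
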