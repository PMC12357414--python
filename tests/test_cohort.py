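"""Entry/exit rules, exclusion vs censoring, and cohort conservation."""

import datetime as dt

import pandas as pd
import pytest

from coprescribe import StudyWindow, build_cohort, generate, scenario_library, study_entry, study_exit
from coprescribe.cohort import apply_exclusion_censoring
from coprescribe._dates import anniversary

from conftest import d, make_tables, simple_patient

WINDOW = StudyWindow()


@pytest.mark.parametrize("registration,uts,birth_year,expected", [
    # registration anniversary binds
    ("2009-06-01", "2005-01-01", 1980, "2010-06-01"),
    # turning 18 binds
    ("1990-01-01", "1990-01-01", 2000, "2018-01-01"),
    # everything collapses to the window start
    ("2009-01-01", "2009-01-01", 1980, "2010-01-01"),
    # up-to-standard anniversary binds
    ("2000-01-01", "2012-03-15", 1980, "2013-03-15"),
])
def test_study_entry_is_latest_candidate(registration, uts, birth_year, expected):
    assert study_entry(d(registration), d(uts), birth_year, WINDOW) == d(expected)


def test_leap_day_anniversary_maps_to_march_first():
    assert anniversary(d("2012-02-29")) == d("2013-03-01")


@pytest.mark.parametrize("death,transfer,last_collection,birth_year,expected", [
    (("2015-03-02"), None, "2019-06-30", 1950, ("2015-03-02", "death")),
    (None, None, "2020-05-01", 1980, ("2019-12-31", "study_end")),
    (None, None, "2019-12-31", 1915, ("2016-01-01", "turned_101")),
    (None, "2013-07-01", "2013-07-01", 1950, ("2013-07-01", "transfer_out")),  # tie
])
def test_study_exit_is_earliest_with_precedence(death, transfer, last_collection,
                                                birth_year, expected):
    got = study_exit(None if death is None else d(death),
                     None if transfer is None else d(transfer),
                     d(last_collection), birth_year, WINDOW)
    assert got == (d(expected[0]), expected[1])


def test_exclusion_before_entry():
    status, *_, cat = apply_exclusion_censoring(
        d("2010-06-01"), d("2019-12-31"), "study_end", (d("2008-01-01"), "cancer"))
    assert (status, cat) == ("excluded", "cancer")


def test_censoring_during_followup_shortens_exit():
    status, entry, exit_, reason = apply_exclusion_censoring(
        d("2010-06-01"), d("2019-12-31"), "study_end",
        (d("2014-02-01"), "heart_failure"))
    assert status == "included"
    assert (exit_, reason) == (d("2014-02-01"), "censor_heart_failure")


def test_event_on_entry_date_censors_to_one_day():
    status, entry, exit_, reason = apply_exclusion_censoring(
        d("2010-06-01"), d("2019-12-31"), "study_end", (d("2010-06-01"), "cancer"))
    assert status == "included"
    assert entry == exit_ == d("2010-06-01")
    assert reason == "censor_cancer"


def test_no_events_leaves_followup_unchanged():
    got = apply_exclusion_censoring(d("2010-06-01"), d("2015-01-01"), "death", None)
    assert got == ("included", d("2010-06-01"), d("2015-01-01"), "death")


def test_late_registration_is_dropped_not_excluded():
    tables = make_tables(patients=[simple_patient(registration="2019-09-01")])
    followup, exclusions, tally = build_cohort(
        tables.patients, tables.practices, tables.clinical, WINDOW)
    assert len(followup) == 0 and len(exclusions) == 0
    assert tally["no_eligible_followup"] == 1


def test_null_scenario_includes_everyone():
    params = scenario_library("null", n_patients=150, seed=2)
    tables, _ = generate(params)
    followup, exclusions, tally = build_cohort(
        tables.patients, tables.practices, tables.clinical, params.window)
    assert tally["included"] == 150
    assert len(exclusions) == 0 and tally["no_eligible_followup"] == 0


def test_conservation_and_window_bounds(typical_small):
    params, tables, _ = typical_small
    followup, exclusions, tally = build_cohort(
        tables.patients, tables.practices, tables.clinical, params.window)
    assert (tally["included"] + tally["no_eligible_followup"]
            + sum(tally["excluded_before_entry"].values())) == tally["input"] \
        == len(tables.patients)
    assert (followup["entry_date"] >= pd.Timestamp(params.window.start)).all()
    assert (followup["exit_date"] <= pd.Timestamp(params.window.end)).all()
    assert (followup["exit_date"] >= followup["entry_date"]).all()


def test_adding_censor_event_never_lengthens_followup(typical_small):
    params, tables, _ = typical_small
    fu1, _, _ = build_cohort(tables.patients, tables.practices, tables.clinical,
                             params.window)
    extra = fu1.iloc[:40]
    mid = extra["entry_date"] + (extra["exit_date"] - extra["entry_date"]) / 2
    clin2 = pd.concat([
        tables.clinical,
        pd.DataFrame({"patient_id": extra["patient_id"],
                      "event_date": mid.dt.normalize(),
                      "code": "C10", "category": "cancer"}),
    ], ignore_index=True)
    fu2, _, _ = build_cohort(tables.patients, tables.practices, clin2, params.window)
    merged = fu1.merge(fu2, on="patient_id", suffixes=("_before", "_after"))
    assert (merged["exit_date_after"] <= merged["exit_date_before"]).all()
    assert len(fu2) <= len(fu1)
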