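"""Overlap events, episodes, thresholds, combinations and contraindications."""

import pandas as pd
import pytest

from coprescribe import (DurationConfig, build_episodes, build_intervals,
                         build_cohort, combination_counts, find_events,
                         flag_contraindicated, merge_same_drug, overlap_days,
                         threshold_filter, upset_membership, StudyWindow)

from conftest import d, make_tables, simple_patient

WINDOW = StudyWindow()


@pytest.mark.parametrize("a,b,expected", [
    (("2015-01-01", "2015-01-28"), ("2015-01-28", "2015-02-25"), 1),  # one shared day
    (("2015-01-01", "2015-01-28"), ("2015-02-01", "2015-02-28"), 0),  # disjoint
    (("2015-01-01", "2015-03-01"), ("2015-01-15", "2015-02-14"), 31), # contained
])
def test_overlap_days(a, b, expected):
    assert overlap_days(d(a[0]), d(a[1]), d(b[0]), d(b[1])) == expected
    assert overlap_days(d(b[0]), d(b[1]), d(a[0]), d(a[1])) == expected


def _events_for(therapy_rows, clinical_rows=(), patients=None):
    tables = make_tables(
        patients=patients or [simple_patient()],
        therapy=therapy_rows, clinical=clinical_rows)
    followup, _, _ = build_cohort(tables.patients, tables.practices,
                                  tables.clinical, WINDOW)
    spans = merge_same_drug(build_intervals(tables.therapy, DurationConfig()))
    from coprescribe import default_codelists
    return find_events(spans, followup, default_codelists()), followup


def test_single_pair_overlap_event():
    events, _ = _events_for([
        ("p1", "codeine", "opioid", "2015-01-01", 112, 4, None),        # Jan1-28
        ("p1", "amitriptyline", "antidepressant", "2014-12-20", 40, 1, None),  # Dec20-Jan28
    ])
    assert len(events) == 1
    e = events.iloc[0]
    assert (str(e["overlap_start"].date()), str(e["overlap_end"].date())) == \
        ("2015-01-01", "2015-01-28")
    assert e["overlap_days"] == 28
    assert not e["contraindicated"]


def test_overlap_after_censor_is_discarded():
    events, followup = _events_for(
        [
            ("p1", "codeine", "opioid", "2016-01-01", 112, 4, None),
            ("p1", "amitriptyline", "antidepressant", "2016-01-01", 28, 1, None),
        ],
        clinical_rows=[("p1", "2015-06-01", "C10", "cancer")],
    )
    assert followup.iloc[0]["exit_reason"] == "censor_cancer"
    assert len(events) == 0


def test_one_opioid_against_two_antidepressants_gives_two_events():
    events, _ = _events_for([
        ("p1", "codeine", "opioid", "2015-01-01", 112, 4, None),
        ("p1", "amitriptyline", "antidepressant", "2015-01-10", 28, 1, None),
        ("p1", "sertraline", "antidepressant", "2015-01-20", 28, 1, None),
    ])
    assert len(events) == 2
    assert set(events["antidepressant_drug"]) == {"amitriptyline", "sertraline"}


def test_events_clipped_to_followup_boundary():
    # entry is 2010-01-01; coverage starting 2009 is clipped at entry
    events, _ = _events_for([
        ("p1", "codeine", "opioid", "2009-12-01", 240, 4, None),          # 60d to Jan29
        ("p1", "amitriptyline", "antidepressant", "2009-12-15", 60, 1, None),
    ])
    assert len(events) == 1
    assert str(events.iloc[0]["overlap_start"].date()) == "2010-01-01"


def test_episode_union_of_overlapping_events():
    events, _ = _events_for([
        ("p1", "codeine", "opioid", "2015-01-01", 112, 4, None),          # Jan1-28
        ("p1", "tramadol", "opioid", "2015-01-20", 112, 4, None),         # Jan20-Feb16
        ("p1", "amitriptyline", "antidepressant", "2015-01-01", 47, 1, None),
    ])
    episodes = build_episodes(events)
    assert len(episodes) == 1
    assert episodes.iloc[0]["episode_days"] == 47
    assert "codeine+amitriptyline" in episodes.iloc[0]["drug_pairs"]
    assert "tramadol+amitriptyline" in episodes.iloc[0]["drug_pairs"]
    # total episode days equal the person's co-prescribed day-set size
    days = set()
    for e in events.itertuples(index=False):
        days |= set(range(e.overlap_start.date().toordinal(),
                          e.overlap_end.date().toordinal() + 1))
    assert episodes["episode_days"].sum() == len(days)


def test_no_events_no_episodes():
    assert len(build_episodes(pd.DataFrame(columns=[
        "patient_id", "opioid_drug", "antidepressant_drug",
        "overlap_start", "overlap_end", "overlap_days", "contraindicated"]))) == 0


def test_threshold_filter_boundary_and_nesting(typical_small):
    from coprescribe import default_codelists, run
    _, tables, _ = typical_small
    res = run(tables, default_codelists())
    ev = res.events
    assert len(threshold_filter(ev, 1)) == len(ev)
    e14 = threshold_filter(ev, 14)
    e28 = threshold_filter(ev, 28)
    assert (e14["overlap_days"] >= 14).all()
    key = ["patient_id", "opioid_drug", "antidepressant_drug", "overlap_start"]
    k14 = set(map(tuple, e14[key].astype(str).values))
    k28 = set(map(tuple, e28[key].astype(str).values))
    kall = set(map(tuple, ev[key].astype(str).values))
    assert k28 <= k14 <= kall
    with pytest.raises(ValueError):
        threshold_filter(ev, 0)


def test_combination_counts_and_upset_table():
    events, _ = _events_for([
        ("p1", "codeine", "opioid", "2015-01-01", 112, 4, None),
        ("p1", "amitriptyline", "antidepressant", "2015-01-01", 28, 1, None),
        ("p1", "codeine", "opioid", "2016-01-01", 112, 4, None),
        ("p1", "amitriptyline", "antidepressant", "2016-01-01", 28, 1, None),
        ("p1", "codeine", "opioid", "2017-01-01", 112, 4, None),
        ("p1", "amitriptyline", "antidepressant", "2017-01-01", 28, 1, None),
    ])
    counts = combination_counts(events)
    assert len(counts) == 1
    assert counts.iloc[0]["n_events"] == 3
    assert counts.iloc[0]["n_people"] == 1
    long = upset_membership(events)
    assert len(long) == 2 * len(events)
    assert set(long["drug"]) == {"codeine", "amitriptyline"}


def test_combination_counts_empty():
    assert combination_counts(pd.DataFrame(columns=[
        "patient_id", "opioid_drug", "antidepressant_drug",
        "overlap_start", "overlap_end", "overlap_days"])).empty


@pytest.mark.parametrize("opioid,antidep,expected", [
    ("tramadol", "phenelzine", True),
    ("methadone", "citalopram", True),
    ("codeine", "amitriptyline", False),
])
def test_contraindicated_pairs(codelists, opioid, antidep, expected):
    assert codelists.is_contraindicated(opioid, antidep) is expected


def test_flag_contraindicated_subset(codelists):
    events, _ = _events_for([
        ("p1", "tramadol", "opioid", "2015-01-01", 112, 4, None),
        ("p1", "phenelzine", "antidepressant", "2015-01-01", 84, 3, None),
        ("p1", "amitriptyline", "antidepressant", "2015-01-01", 28, 1, None),
    ])
    subset, n_people = flag_contraindicated(events, codelists)
    assert set(subset["antidepressant_drug"]) == {"phenelzine"}
    assert n_people == 1


def test_contraindicated_codelist_with_wrong_class_is_fatal():
    from coprescribe import Codelists
    from coprescribe.io import InputError
    with pytest.raises(InputError):
        Codelists({"codeine": "opioid", "amitriptyline": "antidepressant"},
                  frozenset({("amitriptyline", "codeine")}), {})
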