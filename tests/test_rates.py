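"""Person-time splitting, rate arithmetic and exact Poisson intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coprescribe import (StudyWindow, default_codelists, generate, rate_ci,
                         run, scenario_library, split_person_time)
from coprescribe.rates import DAYS_PER_YEAR, incidence_rates, prevalence_rates


def _followup(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "entry_date", "exit_date", "exit_reason"])
    for c in ("entry_date", "exit_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def _attrs(rows):
    return pd.DataFrame(rows, columns=[
        "patient_id", "sex", "birth_year", "townsend", "ethnic_group"])


def test_split_person_time_across_year_boundary():
    fu = _followup([("p1", "2014-07-01", "2015-06-30", "study_end")])
    cells = split_person_time(fu, _attrs([("p1", "female", 1980, 3, "White")]))
    got = cells.set_index("year")["days_in_year"].to_dict()
    assert got == {2014: 184, 2015: 181}
    assert cells.set_index("year")["age_band"].to_dict() == {2014: "18-34", 2015: "35-44"}


def test_split_person_time_single_year_and_age_band():
    fu = _followup([("p1", "2015-03-01", "2015-03-01", "death")])
    cells = split_person_time(fu, _attrs([("p1", "male", 1980, 1, "White")]))
    assert len(cells) == 1
    assert cells.iloc[0]["days_in_year"] == 1
    assert cells.iloc[0]["age_band"] == "35-44"   # age attained on Jan 1 = 35


def test_person_time_conservation(typical_small):
    params, tables, _ = typical_small
    res = run(tables, default_codelists())
    total_fu = ((res.followup["exit_date"] - res.followup["entry_date"]).dt.days + 1).sum()
    assert res.cells["days_in_year"].sum() == total_fu
    # and within every stratification
    for s in ("sex", "age_band", "townsend", "ethnic_group"):
        assert res.cells.groupby(s)["days_in_year"].sum().sum() == total_fu


def test_prevalence_arithmetic_forced_by_definition():
    fu = _followup([(f"p{i}", "2015-01-02", "2016-01-01", "study_end")
                    for i in range(10)])   # exactly 365 days each
    attrs = _attrs([(f"p{i}", "female", 1970, 2, "White") for i in range(10)])
    cells = split_person_time(fu, attrs)
    events = pd.DataFrame({
        "patient_id": ["p0", "p1", "p2", "p3", "p4"],
        "overlap_start": pd.to_datetime(["2015-06-01"] * 5),
        "overlap_end": pd.to_datetime(["2015-06-10"] * 5),
        "overlap_days": [10] * 5,
    })
    rates_ = prevalence_rates(events, cells, strata=())
    row = rates_[(rates_["year"] == 2015) & (rates_["stratum_type"] == "overall")].iloc[0]
    # 5 prevalent persons over (10 x 364)/365.25 + ... person-years in 2015
    py = cells[cells["year"] == 2015]["days_in_year"].sum() / DAYS_PER_YEAR
    assert row["numerator"] == 5
    assert row["rate_per_1000"] == pytest.approx(1000 * 5 / py)
    assert row["ci_low"] <= row["rate_per_1000"] <= row["ci_high"]


def test_no_events_zero_rates_full_denominators():
    fu = _followup([("p1", "2015-01-01", "2015-12-31", "study_end")])
    cells = split_person_time(fu, _attrs([("p1", "female", 1970, 2, "White")]))
    empty = pd.DataFrame(columns=["patient_id", "overlap_start", "overlap_end", "overlap_days"])
    prev = prevalence_rates(empty, cells, strata=())
    assert (prev["numerator"] == 0).all()
    assert (prev["rate_per_1000"] == 0).all()
    assert (prev["ci_low"] == 0).all()
    inc = incidence_rates(empty, cells, [], strata=())
    # incidence denominator equals full follow-up when nothing happens
    assert inc[(inc["year"] == 2015)]["person_years"].iloc[0] == \
        prev[(prev["year"] == 2015)]["person_years"].iloc[0]


def test_incident_event_on_entry_date_counts_one_day_at_risk():
    fu = _followup([("p1", "2015-01-01", "2015-12-31", "study_end")])
    cells = split_person_time(fu, _attrs([("p1", "female", 1970, 2, "White")]))
    events = pd.DataFrame({
        "patient_id": ["p1"],
        "overlap_start": pd.to_datetime(["2015-01-01"]),
        "overlap_end": pd.to_datetime(["2015-01-05"]),
        "overlap_days": [5],
    })
    inc = incidence_rates(events, cells, [], strata=())
    row = inc[inc["year"] == 2015].iloc[0]
    assert row["numerator"] == 1
    assert row["person_years"] == pytest.approx(1 / DAYS_PER_YEAR)


def test_prior_coprescriber_removed_from_numerator_and_denominator():
    fu = _followup([
        ("p1", "2015-01-01", "2015-12-31", "study_end"),
        ("p2", "2015-01-01", "2015-12-31", "study_end"),
    ])
    attrs = _attrs([("p1", "female", 1970, 2, "White"),
                    ("p2", "male", 1960, 3, "White")])
    cells = split_person_time(fu, attrs)
    events = pd.DataFrame({
        "patient_id": ["p1", "p2"],
        "overlap_start": pd.to_datetime(["2015-02-01", "2015-02-01"]),
        "overlap_end": pd.to_datetime(["2015-02-10", "2015-02-10"]),
        "overlap_days": [10, 10],
    })
    inc = incidence_rates(events, cells, ["p2"], strata=())
    row = inc[inc["year"] == 2015].iloc[0]
    assert row["numerator"] == 1
    assert row["person_years"] == pytest.approx(32 / DAYS_PER_YEAR)  # p1 only, to Feb 1


def test_rate_ci_matches_independent_gamma_limits():
    """Exact Poisson limits cross-checked against the chi-square formulation."""
    count, py = 10, 100.0
    lo, hi = rate_ci(count, py)
    lo_chi = stats.chi2.ppf(0.025, 2 * count) / 2 / py * 1000
    hi_chi = stats.chi2.ppf(0.975, 2 * (count + 1)) / 2 / py * 1000
    assert lo == pytest.approx(lo_chi, rel=1e-12)
    assert hi == pytest.approx(hi_chi, rel=1e-12)
    assert lo < 1000 * count / py < hi


def test_rate_ci_zero_count_lower_bound_zero():
    lo, hi = rate_ci(0, 50.0)
    assert lo == 0.0
    assert hi > 0.0
    with pytest.raises(ValueError):
        rate_ci(-1, 50.0)


def test_incidence_numerator_never_exceeds_prevalence(typical_small):
    params, tables, _ = typical_small
    res = run(tables, default_codelists())
    for df in (res.prevalence, res.incidence):
        assert (df["ci_low"] <= df["rate_per_1000"]).all()
        assert (df["rate_per_1000"] <= df["ci_high"] + 1e-9).all()
    key = ["year", "stratum_type", "stratum"]
    merged = res.prevalence.merge(res.incidence, on=key, suffixes=("_prev", "_inc"))
    assert (merged["numerator_inc"] <= merged["numerator_prev"]).all()
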