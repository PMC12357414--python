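import datetime as dt

import pandas as pd
import pytest

from coprescribe import StudyWindow, Tables, default_codelists, generate, scenario_library

WINDOW = StudyWindow()


@pytest.fixture(scope="session")
def codelists():
    return default_codelists()


def make_tables(patients=(), therapy=(), clinical=(), practices=None) -> Tables:
    """Handcrafted input tables with sensible defaults.

    ``patients`` rows: (patient_id, sex, birth_year, registration, transfer,
    death, practice_id, ethnicity, townsend_person); ``therapy`` rows:
    (patient_id, drug_name, drug_class, issue_date, quantity, daily_dose,
    stated_duration); ``clinical`` rows: (patient_id, event_date, code,
    category). Dates may be ISO strings.
    """
    if practices is None:
        practices = [("pr1", "London", "2005-01-01", "2019-12-31", 3)]
    prac = pd.DataFrame(practices, columns=[
        "practice_id", "region", "uts_date", "last_collection_date",
        "townsend_practice"])
    for c in ("uts_date", "last_collection_date"):
        prac[c] = pd.to_datetime(prac[c])
    prac["townsend_practice"] = prac["townsend_practice"].astype("Int64")

    pats = pd.DataFrame(list(patients), columns=[
        "patient_id", "sex", "birth_year", "registration_date",
        "transfer_out_date", "death_date", "practice_id", "ethnicity",
        "townsend_person"])
    for c in ("registration_date", "transfer_out_date", "death_date"):
        pats[c] = pd.to_datetime(pats[c])
    pats["townsend_person"] = pats["townsend_person"].astype("Int64")

    ther = pd.DataFrame(list(therapy), columns=[
        "patient_id", "drug_name", "drug_class", "issue_date", "quantity",
        "daily_dose", "stated_duration_days"])
    ther["issue_date"] = pd.to_datetime(ther["issue_date"])
    for c in ("quantity", "daily_dose"):
        ther[c] = ther[c].astype(float)
    ther["stated_duration_days"] = ther["stated_duration_days"].astype("Int64")

    clin = pd.DataFrame(list(clinical), columns=[
        "patient_id", "event_date", "code", "category"])
    clin["event_date"] = pd.to_datetime(clin["event_date"])

    hes = pd.DataFrame(columns=["patient_id", "ethnicity"])
    return Tables(pats, prac, ther, clin, hes)


def simple_patient(pid="p1", birth_year=1970, registration="2005-01-01",
                   transfer=None, death=None, practice="pr1"):
    return (pid, "female", birth_year, registration, transfer, death,
            practice, "White", 3)


@pytest.fixture(scope="session")
def typical_small():
    """A modest 'typical' cohort plus its ground truth, shared read-only."""
    params = scenario_library("typical", n_patients=400, seed=11)
    tables, truth = generate(params)
    return params, tables, truth


def d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)
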