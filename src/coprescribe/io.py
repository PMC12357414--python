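"""Readers, writers and attribute-resolution helpers for the input tables.

The pipeline consumes five CSV tables shaped like a CPRD GOLD extract —
patient, practice, therapy (prescriptions), clinical (coded events) and an
optional linked hospital (HES) ethnicity table — plus three codelist CSVs
that form the terminology boundary of the package:

* ``drug_classes.csv``  — drug name -> {opioid, antidepressant}
* ``contraindicated.csv`` — (opioid, antidepressant) pairs flagged as high
  interaction risk
* ``clinical_codes.csv``  — clinical code -> event category

Dates are ISO-8601 (``YYYY-MM-DD``); empty optional fields are empty strings.
Drug-name matching against the codelist is case-insensitive and exact.

Row-level validation is deliberately strict but non-silent: rows that violate
a type invariant (unparseable date, non-positive quantity) are rejected and
reported per table; therapy rows whose drug name is not in the codelist are
dropped and counted separately. Structural problems that make the analysis
uncomputable — a missing file, duplicate patient ids, a patient pointing at
an unknown practice — are fatal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SEXES = ("male", "female")
ETHNIC_GROUPS = (
    "Asian/British Asian",
    "Black/Black British",
    "Mixed",
    "Other",
    "White",
)
NOT_KNOWN = "not known"

DRUG_CLASSES = ("opioid", "antidepressant")

CENSOR_CATEGORIES = ("cancer", "terminal_illness", "heart_failure", "opioid_misuse")
INDICATION_CATEGORIES = ("depression", "anxiety_phobia", "neuropathic_pain")
CLINICAL_CATEGORIES = CENSOR_CATEGORIES + INDICATION_CATEGORIES

PATIENT_COLUMNS = [
    "patient_id", "sex", "birth_year", "registration_date", "transfer_out_date",
    "death_date", "practice_id", "ethnicity", "townsend_person",
]
PRACTICE_COLUMNS = [
    "practice_id", "region", "uts_date", "last_collection_date", "townsend_practice",
]
THERAPY_COLUMNS = [
    "patient_id", "drug_name", "issue_date", "quantity", "daily_dose",
    "stated_duration_days",
]
CLINICAL_COLUMNS = ["patient_id", "event_date", "code"]
HES_COLUMNS = ["patient_id", "ethnicity"]


class InputError(ValueError):
    """Fatal problem with an input file (structure, not a single row)."""


@dataclasses.dataclass(frozen=True)
class Codelists:
    """Terminology boundary: drug classes, contraindicated pairs, clinical codes.

    ``drug_class_map`` keys are lower-cased drug names. ``contraindicated_pairs``
    holds lower-cased ``(opioid_name, antidepressant_name)`` tuples; both
    members must exist in ``drug_class_map`` with the matching class.
    """

    drug_class_map: Mapping[str, str]
    contraindicated_pairs: frozenset
    clinical_map: Mapping[str, str]

    def __post_init__(self):
        for name, cls in self.drug_class_map.items():
            if cls not in DRUG_CLASSES:
                raise InputError(f"unknown drug class {cls!r} for {name!r}")
        for op, ad in self.contraindicated_pairs:
            if self.drug_class_map.get(op) != "opioid":
                raise InputError(f"contraindicated pair member {op!r} is not a listed opioid")
            if self.drug_class_map.get(ad) != "antidepressant":
                raise InputError(
                    f"contraindicated pair member {ad!r} is not a listed antidepressant"
                )
        for code, cat in self.clinical_map.items():
            if cat not in CLINICAL_CATEGORIES:
                raise InputError(f"unknown clinical category {cat!r} for code {code!r}")

    def drug_class(self, drug_name: str) -> str | None:
        return self.drug_class_map.get(drug_name.lower())

    def is_contraindicated(self, opioid: str, antidepressant: str) -> bool:
        return (opioid.lower(), antidepressant.lower()) in self.contraindicated_pairs


@dataclasses.dataclass
class Tables:
    """Validated, typed input tables plus the row-level validation log."""

    patients: pd.DataFrame
    practices: pd.DataFrame
    therapy: pd.DataFrame
    clinical: pd.DataFrame
    hes_ethnicity: pd.DataFrame
    log: dict = dataclasses.field(default_factory=dict)
    rejections: dict = dataclasses.field(default_factory=dict)


def read_codelists(drug_classes_path, contraindicated_path, clinical_codes_path) -> Codelists:
    dc = _read_csv(drug_classes_path, ["drug_name", "class"])
    ci = _read_csv(contraindicated_path, ["opioid", "antidepressant"])
    cc = _read_csv(clinical_codes_path, ["code", "category"])
    drug_map = {str(r.drug_name).lower(): str(r["class"]) for _, r in dc.iterrows()}
    pairs = frozenset(
        (str(r.opioid).lower(), str(r.antidepressant).lower()) for _, r in ci.iterrows()
    )
    clin_map = {str(r.code): str(r.category) for _, r in cc.iterrows()}
    return Codelists(drug_map, pairs, clin_map)


def write_codelists(codelists: Codelists, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(codelists.drug_class_map.items()), columns=["drug_name", "class"]
    ).to_csv(out / "drug_classes.csv", index=False)
    pd.DataFrame(
        sorted(codelists.contraindicated_pairs), columns=["opioid", "antidepressant"]
    ).to_csv(out / "contraindicated.csv", index=False)
    pd.DataFrame(
        sorted(codelists.clinical_map.items()), columns=["code", "category"]
    ).to_csv(out / "clinical_codes.csv", index=False)


def _read_csv(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def _parse_dates(raw: pd.Series) -> pd.Series:
    return pd.to_datetime(raw.replace("", pd.NA), format="%Y-%m-%d", errors="coerce")


def _parse_num(raw: pd.Series) -> pd.Series:
    return pd.to_numeric(raw.replace("", pd.NA), errors="coerce")


def read_tables(paths: Mapping[str, object], codelists: Codelists) -> Tables:
    """Read and validate the five input tables.

    ``paths`` maps table names (``patient``, ``practice``, ``therapy``,
    ``clinical`` and optionally ``hes_ethnicity``) to file paths. Rows that
    violate row-level invariants are rejected (collected in
    ``Tables.rejections`` with a reason); therapy/clinical rows whose drug
    name or code is absent from the codelists are dropped and counted.
    The per-table ``log`` satisfies ``input == accepted + rejected + dropped``.
    """
    log: dict = {}
    rejections: dict = {}

    # --- practice ---------------------------------------------------------
    raw = _read_csv(paths["practice"], PRACTICE_COLUMNS)
    uts = _parse_dates(raw["uts_date"])
    lcd = _parse_dates(raw["last_collection_date"])
    quint = _parse_num(raw["townsend_practice"])
    bad_quint = ~quint.isin([1, 2, 3, 4, 5])
    if bad_quint.any():
        raise InputError("practice table: townsend_practice outside 1-5")
    bad = uts.isna() | lcd.isna() | (uts > lcd)
    practices = pd.DataFrame({
        "practice_id": raw["practice_id"],
        "region": raw["region"],
        "uts_date": uts,
        "last_collection_date": lcd,
        "townsend_practice": quint.astype("Int64"),
    })[~bad].reset_index(drop=True)
    if practices["practice_id"].duplicated().any():
        raise InputError("practice table: duplicate practice_id")
    _log(log, rejections, "practice", raw, bad, reasons="invalid or inconsistent dates")

    # --- patient ----------------------------------------------------------
    raw = _read_csv(paths["patient"], PATIENT_COLUMNS)
    if raw["patient_id"].duplicated().any():
        raise InputError("patient table: duplicate patient_id")
    eth = raw["ethnicity"].replace("", pd.NA)
    bad_eth = eth.dropna()[~eth.dropna().isin(ETHNIC_GROUPS)]
    if len(bad_eth):
        raise InputError(f"patient table: unrecognised ethnicity labels {sorted(set(bad_eth))}")
    tq = _parse_num(raw["townsend_person"])
    if (~tq.isna() & ~tq.isin([1, 2, 3, 4, 5])).any():
        raise InputError("patient table: townsend_person outside 1-5")
    reg = _parse_dates(raw["registration_date"])
    tout = _parse_dates(raw["transfer_out_date"])
    death = _parse_dates(raw["death_date"])
    byear = _parse_num(raw["birth_year"])
    bad = (
        reg.isna()
        | byear.isna()
        | ~raw["sex"].isin(SEXES)
        | ((raw["transfer_out_date"] != "") & tout.isna())
        | ((raw["death_date"] != "") & death.isna())
        | (tout.notna() & (reg > tout))
        | (death.notna() & (reg > death))
    )
    patients = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "sex": raw["sex"],
        "birth_year": byear.astype("Int64"),
        "registration_date": reg,
        "transfer_out_date": tout,
        "death_date": death,
        "practice_id": raw["practice_id"],
        "ethnicity": eth,
        "townsend_person": tq.astype("Int64"),
    })[~bad].reset_index(drop=True)
    patients["birth_year"] = patients["birth_year"].astype(int)
    unknown_practice = ~patients["practice_id"].isin(practices["practice_id"])
    if unknown_practice.any():
        raise InputError(
            "patient table: practice_id without a practice row for "
            f"{sorted(patients.loc[unknown_practice, 'patient_id'])[:5]}"
        )
    _log(log, rejections, "patient", raw, bad, reasons="invalid sex/date/ordering")

    # --- therapy ----------------------------------------------------------
    raw = _read_csv(paths["therapy"], THERAPY_COLUMNS)
    issue = _parse_dates(raw["issue_date"])
    qty = _parse_num(raw["quantity"])
    dose = _parse_num(raw["daily_dose"])
    stated = _parse_num(raw["stated_duration_days"])
    cls = raw["drug_name"].str.lower().map(codelists.drug_class_map)
    unmapped = cls.isna()
    bad = (
        issue.isna()
        | qty.isna()
        | (qty <= 0)
        | (dose.notna() & (dose <= 0))
        | (stated.notna() & (stated < 1))
    ) & ~unmapped
    keep = ~bad & ~unmapped
    therapy = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "drug_name": raw["drug_name"].str.lower(),
        "drug_class": cls,
        "issue_date": issue,
        "quantity": qty,
        "daily_dose": dose,
        "stated_duration_days": stated.astype("Int64"),
    })[keep].reset_index(drop=True)
    _log(log, rejections, "therapy", raw, bad,
         reasons="invalid date/quantity/dose", dropped=unmapped)

    # --- clinical ---------------------------------------------------------
    raw = _read_csv(paths["clinical"], CLINICAL_COLUMNS)
    edate = _parse_dates(raw["event_date"])
    cat = raw["code"].map(codelists.clinical_map)
    unmapped = cat.isna()
    bad = edate.isna() & ~unmapped
    clinical = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "event_date": edate,
        "code": raw["code"],
        "category": cat,
    })[~bad & ~unmapped].reset_index(drop=True)
    _log(log, rejections, "clinical", raw, bad,
         reasons="unparseable event_date", dropped=unmapped)

    # --- hes ethnicity (optional) -----------------------------------------
    if "hes_ethnicity" in paths and Path(paths["hes_ethnicity"]).exists():
        raw = _read_csv(paths["hes_ethnicity"], HES_COLUMNS)
        heth = raw["ethnicity"].replace("", pd.NA)
        bad_labels = heth.dropna()[~heth.dropna().isin(ETHNIC_GROUPS)]
        if len(bad_labels):
            raise InputError(
                f"hes_ethnicity: unrecognised labels {sorted(set(bad_labels))}"
            )
        hes = pd.DataFrame({"patient_id": raw["patient_id"], "ethnicity": heth})
        hes = hes[hes["ethnicity"].notna()].reset_index(drop=True)
        _log(log, rejections, "hes_ethnicity", raw, heth.isna(), reasons="empty label")
    else:
        hes = pd.DataFrame(columns=HES_COLUMNS)
        log["hes_ethnicity"] = {"input": 0, "accepted": 0, "rejected": 0, "dropped_unmapped": 0}

    return Tables(patients, practices, therapy, clinical, hes, log, rejections)


def _log(log, rejections, name, raw, bad, reasons="", dropped=None):
    n_drop = int(dropped.sum()) if dropped is not None else 0
    log[name] = {
        "input": len(raw),
        "accepted": len(raw) - int(bad.sum()) - n_drop,
        "rejected": int(bad.sum()),
        "dropped_unmapped": n_drop,
    }
    if bad.any():
        rej = raw[np.asarray(bad)].copy()
        rej["reason"] = reasons
        rejections[name] = rej


_DATE_COLS = {
    "patient": ["registration_date", "transfer_out_date", "death_date"],
    "practice": ["uts_date", "last_collection_date"],
    "therapy": ["issue_date"],
    "clinical": ["event_date"],
    "hes_ethnicity": [],
}


def write_tables(tables: Tables, out_dir) -> dict:
    """Write the five tables back to CSV in the documented dialect.

    Returns the mapping of table name -> path, suitable for ``read_tables``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "patient": tables.patients[PATIENT_COLUMNS],
        "practice": tables.practices[PRACTICE_COLUMNS],
        "therapy": tables.therapy[THERAPY_COLUMNS],
        "clinical": tables.clinical[CLINICAL_COLUMNS],
        "hes_ethnicity": tables.hes_ethnicity[HES_COLUMNS],
    }
    paths = {}
    for name, df in frames.items():
        df = df.copy()
        for c in _DATE_COLS[name]:
            df[c] = df[c].dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%g", na_rep="")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# attribute resolution


def resolve_ethnicity(primary, hes) -> str:
    """Primary-care ethnicity takes precedence; hospital (HES) record fills
    gaps; otherwise "not known"."""
    for label in (primary, hes):
        if label is None or (isinstance(label, float) and np.isnan(label)) or label is pd.NA:
            continue
        if label == "":
            continue
        if label not in ETHNIC_GROUPS:
            raise InputError(f"unrecognised ethnicity label {label!r}")
        return label
    return NOT_KNOWN


def resolve_deprivation(person, practice) -> int:
    """Person-level Townsend quintile, falling back to the practice level."""
    for q in (person, practice):
        if q is None or q is pd.NA or (isinstance(q, float) and np.isnan(q)):
            continue
        q = int(q)
        if not 1 <= q <= 5:
            raise InputError(f"Townsend quintile outside 1-5: {q}")
        return q
    raise InputError("no Townsend quintile available (practice value required)")


def patient_attributes(tables: Tables) -> pd.DataFrame:
    """Per-patient analysis attributes with resolution applied.

    Adds ``ethnic_group`` (five groups or "not known"), ``townsend``
    (person-level with practice fallback) and ``region`` to the patient frame.
    """
    pts = tables.patients.merge(
        tables.practices[["practice_id", "region", "townsend_practice"]],
        on="practice_id", how="left", validate="many_to_one",
    )
    hes = tables.hes_ethnicity.drop_duplicates("patient_id").rename(
        columns={"ethnicity": "ethnicity_hes"}
    )
    pts = pts.merge(hes, on="patient_id", how="left")
    pts["ethnic_group"] = [
        resolve_ethnicity(p, h)
        for p, h in zip(pts["ethnicity"], pts.get("ethnicity_hes", pd.Series(dtype=object)))
    ]
    pts["townsend"] = [
        resolve_deprivation(p, q)
        for p, q in zip(pts["townsend_person"], pts["townsend_practice"])
    ]
    return pts
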