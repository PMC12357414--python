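"""Context descriptors for incident co-prescription and the cohort summary.

For each person with an incident (first) co-prescription event these
operations establish which drug class was started first (using the full
prescription history supplied, including lookback before study entry),
whether an opioid-first person was a long-term opioid user at the first
co-prescription, and which antidepressant indications (depression,
anxiety/phobias, neuropathic pain) were on record on or before that date.

"Long-term opioid use" means the first opioid issue was at least 365 days
before the first co-prescription AND opioid coverage over that span was
continuous up to a configurable gap tolerance (default 90 days between
consecutive coverage spans) — a first-issue date alone would call a single
script from years earlier "long-term".
"""

from __future__ import annotations

import pandas as pd

from .cohort import age_band
from .io import ETHNIC_GROUPS, INDICATION_CATEGORIES, NOT_KNOWN

DEFAULT_MAX_GAP_DAYS = 90


def order_of_initiation(therapy: pd.DataFrame, first_event_date) -> str:
    """Which class was prescribed first, among issues on or before the event.

    Returns ``antidepressant_first``, ``opioid_first`` or ``same_day``.
    A person with a co-prescription necessarily has both classes on record.
    """
    hist = therapy[therapy["issue_date"] <= first_event_date]
    firsts = hist.groupby("drug_class")["issue_date"].min()
    if "opioid" not in firsts or "antidepressant" not in firsts:
        raise ValueError("co-prescribed person lacks history of one drug class")
    if firsts["antidepressant"] < firsts["opioid"]:
        return "antidepressant_first"
    if firsts["opioid"] < firsts["antidepressant"]:
        return "opioid_first"
    return "same_day"


def long_term_opioid(opioid_spans: pd.DataFrame, first_event_date,
                     max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> bool:
    """True when opioid use was long-term (>= 12 months, continuous) at the event.

    ``opioid_spans`` are the person's merged opioid coverage spans,
    unclipped. Both clauses must hold: the earliest span starts at least
    365 days before ``first_event_date``, and no uncovered gap between
    consecutive spans that begin on or before the event exceeds
    ``max_gap_days``.
    """
    spans = opioid_spans[opioid_spans["start"] <= first_event_date]
    if spans.empty:
        return False
    spans = spans.sort_values("start")
    if (first_event_date - spans["start"].iloc[0]).days < 365:
        return False
    gaps = (spans["start"].shift(-1) - spans["end"]).dt.days - 1
    return not (gaps.dropna() > max_gap_days).any()


def indications_before(clinical: pd.DataFrame, first_event_date) -> dict:
    """Antidepressant-indication flags on or before the first co-prescription."""
    hist = clinical[clinical["event_date"] <= first_event_date]
    flags = {c: bool((hist["category"] == c).any()) for c in INDICATION_CATEGORIES}
    flags["any_indication"] = any(flags.values())
    return flags


def incident_context(events: pd.DataFrame, therapy: pd.DataFrame,
                     opioid_spans: pd.DataFrame, clinical: pd.DataFrame,
                     prior_patient_ids=(), max_gap_days: int = DEFAULT_MAX_GAP_DAYS,
                     ) -> pd.DataFrame:
    """Per-incident-person context table.

    One row per person with an incident co-prescription (prior
    co-prescribers removed): first event date, order of initiation,
    long-term-opioid flag (False unless opioid-first, by contract) and
    indication flags.
    """
    prior = set(prior_patient_ids)
    ev = events[~events["patient_id"].isin(prior)]
    if ev.empty:
        return pd.DataFrame(columns=[
            "patient_id", "first_event_date", "order", "long_term_opioid",
            *INDICATION_CATEGORIES, "any_indication",
        ])
    first = ev.groupby("patient_id")["overlap_start"].min()
    t_by = dict(iter(therapy.groupby("patient_id"))) if len(therapy) else {}
    o_by = dict(iter(opioid_spans.groupby("patient_id"))) if len(opioid_spans) else {}
    c_by = dict(iter(clinical.groupby("patient_id"))) if len(clinical) else {}
    empty_clin = clinical.iloc[0:0]

    rows = []
    for pid, fed in first.items():
        order = order_of_initiation(t_by[pid], fed)
        lto = order == "opioid_first" and long_term_opioid(o_by[pid], fed, max_gap_days)
        flags = indications_before(c_by.get(pid, empty_clin), fed)
        rows.append({"patient_id": pid, "first_event_date": fed, "order": order,
                     "long_term_opioid": bool(lto), **flags})
    return pd.DataFrame(rows)


_CHARACTERISTICS = [
    ("sex", ("male", "female")),
    ("age_band", None),       # filled from cohort.AGE_BAND_LABELS at call
    ("region", None),
    ("townsend", (1, 2, 3, 4, 5)),
    ("ethnicity_known", ("Not known", "Known")),
    ("ethnic_group", ETHNIC_GROUPS),
]


def characteristics_table(attributes: pd.DataFrame, followup: pd.DataFrame,
                          coprescribed_ids) -> pd.DataFrame:
    """Two-way cohort description by co-prescription status.

    One row per characteristic category with counts and percentages in the
    not-co-prescribed ("no"), co-prescribed ("yes") and total columns. Age
    is the band attained in the entry year. Ethnic-group percentages are of
    the known-ethnicity total; all other percentages are of the column
    total.
    """
    from .cohort import AGE_BAND_LABELS

    df = followup[["patient_id", "entry_date"]].merge(
        attributes[["patient_id", "sex", "birth_year", "region", "townsend",
                    "ethnic_group"]],
        on="patient_id", how="left", validate="one_to_one",
    )
    df["age_band"] = [
        age_band(y - b) for y, b in zip(df["entry_date"].dt.year, df["birth_year"])
    ]
    df["ethnicity_known"] = (df["ethnic_group"] != NOT_KNOWN).map(
        {True: "Known", False: "Not known"}
    )
    df["co"] = df["patient_id"].isin(set(coprescribed_ids)).map({True: "yes", False: "no"})

    totals = {c: (df["co"] == c).sum() for c in ("no", "yes")}
    totals["total"] = len(df)
    known = df[df["ethnicity_known"] == "Known"]
    known_totals = {c: (known["co"] == c).sum() for c in ("no", "yes")}
    known_totals["total"] = len(known)

    rows = []
    for char, categories in _CHARACTERISTICS:
        if char == "age_band":
            categories = AGE_BAND_LABELS
        elif char == "region":
            categories = sorted(df["region"].dropna().unique())
        base = known if char == "ethnic_group" else df
        denom = known_totals if char == "ethnic_group" else totals
        for cat in categories:
            rec = {"characteristic": char, "category": cat}
            for col, sub in (("no", base[base["co"] == "no"]),
                             ("yes", base[base["co"] == "yes"]),
                             ("total", base)):
                n = int((sub[char] == cat).sum())
                rec[f"{col}_n"] = n
                rec[f"{col}_pct"] = 100.0 * n / denom[col] if denom[col] else 0.0
            rows.append(rec)
    return pd.DataFrame(rows)
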