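"""Opioid x antidepressant overlap detection.

Co-prescribing is defined as an opioid coverage span and an antidepressant
coverage span overlapping by one or more days inside the person's follow-up.
Two granularities are produced:

* **events** — one row per (opioid drug x antidepressant drug x maximal
  intersection interval), the unit for combination counts, overlap-length
  summaries and contraindication flags;
* **episodes** — per-person maximal unions of event intervals, the unit for
  person-level duration questions ("lasted at least 365 days").

Spans are clipped to follow-up *before* intersection, so censoring shortens
or removes events deterministically.
"""

from __future__ import annotations

import pandas as pd

from .intervals import _merge_sorted
from .io import Codelists

EVENT_COLUMNS = [
    "patient_id", "opioid_drug", "antidepressant_drug",
    "overlap_start", "overlap_end", "overlap_days", "contraindicated",
]


def overlap_days(a_start, a_end, b_start, b_end) -> int:
    """Days shared by two closed date intervals; 0 when disjoint."""
    lo = max(a_start, b_start)
    hi = min(a_end, b_end)
    return max(0, (hi - lo).days + 1)


def clip_to_followup(spans: pd.DataFrame, followup: pd.DataFrame) -> pd.DataFrame:
    """Clip coverage spans to [entry, exit]; drop spans left empty.

    Persons without follow-up (excluded or ineligible) lose all spans.
    """
    df = spans.merge(
        followup[["patient_id", "entry_date", "exit_date"]], on="patient_id", how="inner"
    )
    df["start"] = df[["start", "entry_date"]].max(axis=1)
    df["end"] = df[["end", "exit_date"]].min(axis=1)
    df = df[df["start"] <= df["end"]]
    return df.drop(columns=["entry_date", "exit_date"]).reset_index(drop=True)


def find_events(spans: pd.DataFrame, followup: pd.DataFrame,
                codelists: Codelists | None = None) -> pd.DataFrame:
    """Pairwise overlap events between opioid and antidepressant spans.

    ``spans`` are merged per-drug coverage spans (see
    :func:`coprescribe.intervals.merge_same_drug`) for any number of
    patients, *not* yet clipped. One event per maximal intersection interval
    of an (opioid drug, antidepressant drug) pair within follow-up. When
    ``codelists`` is given the ``contraindicated`` flag is filled in.
    """
    clipped = clip_to_followup(spans, followup)
    op = clipped[clipped["drug_class"] == "opioid"]
    ad = clipped[clipped["drug_class"] == "antidepressant"]
    if op.empty or ad.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)

    pairs = op.merge(ad, on="patient_id", suffixes=("_op", "_ad"))
    start = pairs[["start_op", "start_ad"]].max(axis=1)
    end = pairs[["end_op", "end_ad"]].min(axis=1)
    keep = start <= end
    events = pd.DataFrame({
        "patient_id": pairs["patient_id"],
        "opioid_drug": pairs["drug_name_op"],
        "antidepressant_drug": pairs["drug_name_ad"],
        "start": start,
        "end": end,
    })[keep]

    # per-drug spans are separated by uncovered days, so pair intersections
    # are already maximal; the union-merge below is a cheap safety net that
    # also deduplicates identical rows
    events = _merge_sorted(
        events, ["patient_id", "opioid_drug", "antidepressant_drug"], gap=0
    )
    events = events.rename(columns={"start": "overlap_start", "end": "overlap_end"})
    events["overlap_days"] = (events["overlap_end"] - events["overlap_start"]).dt.days + 1
    if codelists is not None:
        events["contraindicated"] = [
            codelists.is_contraindicated(o, a)
            for o, a in zip(events["opioid_drug"], events["antidepressant_drug"])
        ]
    else:
        events["contraindicated"] = False
    events = events.sort_values(
        ["patient_id", "overlap_start", "opioid_drug", "antidepressant_drug"],
        kind="stable",
    ).reset_index(drop=True)
    return events[EVENT_COLUMNS]


def build_episodes(events: pd.DataFrame) -> pd.DataFrame:
    """Merge a person's events into disjoint co-prescribing episodes.

    Episodes are drug-agnostic maximal unions (gap 0) of event intervals;
    ``drug_pairs`` lists the contributing combinations.
    """
    if events.empty:
        return pd.DataFrame(columns=["patient_id", "start", "end", "episode_days", "drug_pairs"])
    df = events.rename(columns={"overlap_start": "start", "overlap_end": "end"})
    episodes = _merge_sorted(df, ["patient_id"], gap=0)
    episodes["episode_days"] = (episodes["end"] - episodes["start"]).dt.days + 1

    # attach contributing pairs per episode
    df = df.merge(episodes.reset_index(names="episode_ix"),
                  on="patient_id", suffixes=("", "_ep"))
    inside = (df["start"] >= df["start_ep"]) & (df["end"] <= df["end_ep"])
    pairs = (
        df[inside]
        .assign(pair=lambda d: d["opioid_drug"] + "+" + d["antidepressant_drug"])
        .groupby("episode_ix")["pair"]
        .apply(lambda s: ";".join(sorted(set(s))))
    )
    episodes["drug_pairs"] = episodes.index.map(pairs)
    return episodes


def threshold_filter(df: pd.DataFrame, min_days: int, column: str | None = None) -> pd.DataFrame:
    """Keep events/episodes lasting at least ``min_days`` days.

    Antitone in ``min_days``: a larger threshold always yields a subset.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    if column is None:
        column = "overlap_days" if "overlap_days" in df.columns else "episode_days"
    return df[df[column] >= min_days].reset_index(drop=True)


def combination_counts(events: pd.DataFrame) -> pd.DataFrame:
    """Event and distinct-person counts per drug combination, sorted.

    Descending by event count (ties: person count, then name) — the table
    behind an UpSet-style combination figure.
    """
    if events.empty:
        return pd.DataFrame(
            columns=["opioid_drug", "antidepressant_drug", "n_events", "n_people"]
        )
    grp = events.groupby(["opioid_drug", "antidepressant_drug"])
    out = grp.agg(
        n_events=("patient_id", "size"), n_people=("patient_id", "nunique")
    ).reset_index()
    return out.sort_values(
        ["n_events", "n_people", "opioid_drug", "antidepressant_drug"],
        ascending=[False, False, True, True], kind="stable",
    ).reset_index(drop=True)


def upset_membership(events: pd.DataFrame) -> pd.DataFrame:
    """Long-format membership table (event id x member drug) for UpSet plots."""
    ev = events.reset_index(names="event_id")
    long = pd.concat([
        ev[["event_id", "patient_id", "opioid_drug"]]
        .rename(columns={"opioid_drug": "drug"}).assign(drug_class="opioid"),
        ev[["event_id", "patient_id", "antidepressant_drug"]]
        .rename(columns={"antidepressant_drug": "drug"}).assign(drug_class="antidepressant"),
    ])
    return long.sort_values(["event_id", "drug_class"],
                            ascending=[True, False], kind="stable").reset_index(drop=True)


def flag_contraindicated(events: pd.DataFrame, codelists: Codelists):
    """Contraindicated subset of events plus the distinct-person count."""
    flagged = events.assign(contraindicated=[
        codelists.is_contraindicated(o, a)
        for o, a in zip(events["opioid_drug"], events["antidepressant_drug"])
    ])
    subset = flagged[flagged["contraindicated"]].reset_index(drop=True)
    return subset, subset["patient_id"].nunique()


def prior_coprescription(spans: pd.DataFrame, followup: pd.DataFrame) -> pd.Series:
    """Patient ids with any opioid/antidepressant overlap before study entry.

    Uses *unclipped* spans: lookback prescriptions issued before entry count.
    A day strictly before entry covered by both classes marks the person as
    a prior co-prescriber (they are removed from incidence analyses).
    """
    df = spans.merge(followup[["patient_id", "entry_date"]], on="patient_id", how="inner")
    df = df[df["start"] < df["entry_date"]].copy()
    df["end"] = df[["end"]].min(axis=1).clip(upper=df["entry_date"] - pd.Timedelta(days=1))
    df = df[df["start"] <= df["end"]]
    op = df[df["drug_class"] == "opioid"]
    ad = df[df["drug_class"] == "antidepressant"]
    if op.empty or ad.empty:
        return pd.Series([], dtype=object)
    pairs = op.merge(ad, on="patient_id", suffixes=("_op", "_ad"))
    hit = (
        pairs[["start_op", "start_ad"]].max(axis=1)
        <= pairs[["end_op", "end_ad"]].min(axis=1)
    )
    return pd.Series(sorted(pairs.loc[hit, "patient_id"].unique()), dtype=object)
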