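"""Estimate prescription durations and merge scripts into coverage spans.

Three codeine scripts for one person: two overlapping (a renewal issued a
week early) and one after a long break. Duration comes from quantity and
daily dose; the overlapping pair is unioned into a single drug era with no
stockpiling.
"""

import pandas as pd

from coprescribe import DurationConfig, build_intervals, merge_same_drug

therapy = pd.DataFrame({
    "patient_id": ["p1"] * 3,
    "drug_name": ["codeine"] * 3,
    "drug_class": ["opioid"] * 3,
    "issue_date": pd.to_datetime(["2015-01-01", "2015-01-22", "2015-06-01"]),
    "quantity": [112.0, 112.0, 112.0],     # tablets
    "daily_dose": [4.0, 4.0, None],        # last script: dose not recorded
    "stated_duration_days": pd.array([None, None, None], dtype="Int64"),
})

intervals = build_intervals(therapy, DurationConfig())
print(intervals[["start", "end", "duration_days", "duration_source"]].to_string())
# 112 tablets at 4/day -> 28 days; the third script falls back to the drug
# median (28 days here) because its daily dose is missing.

spans = merge_same_drug(intervals, gap=0)
print()
print(spans[["start", "end", "span_days"]].to_string())
# Two eras: Jan 1 - Feb 18 (union of the overlapping scripts, 49 days,
# surplus tablets are NOT carried forward) and the separate June era.
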