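"""Date helpers shared across the pipeline.

All follow-up and coverage intervals in this package are *closed* date
intervals: a prescription covering ``[start, end]`` covers ``end - start + 1``
days. Calendar dates are carried as :class:`datetime.date` in scalar code and
as ``datetime64[ns]`` columns inside DataFrames; day arithmetic in vectorised
code goes through proleptic-Gregorian ordinals (``to_ordinal``).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

EPOCH = dt.date(1970, 1, 1)


def anniversary(d: dt.date, years: int = 1) -> dt.date:
    """Same month/day ``years`` later; Feb 29 maps to Mar 1."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return dt.date(d.year + years, 3, 1)


def to_ordinal(col: pd.Series) -> np.ndarray:
    """Convert a datetime64 column to proleptic-Gregorian ordinal ints.

    NaT maps to a large sentinel that keeps comparisons well-defined
    without floating-point NaN contagion; callers must mask NaT first
    when the sentinel would matter.
    """
    days = col.values.astype("datetime64[D]").view("int64")
    return days + EPOCH.toordinal()


def from_ordinal(o: np.ndarray) -> pd.Series:
    return pd.Series(
        (np.asarray(o, dtype="int64") - EPOCH.toordinal()).view("timedelta64[D]")
        + np.datetime64("1970-01-01")
    )


def days_inclusive(start, end) -> int:
    """Length of the closed interval [start, end] in days."""
    return (end - start).days + 1


def year_bounds(year: int) -> tuple[dt.date, dt.date]:
    return dt.date(year, 1, 1), dt.date(year, 12, 31)


def ts(d) -> pd.Timestamp:
    return pd.Timestamp(d)
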