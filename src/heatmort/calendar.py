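"""Calendar-day bookkeeping for department-day panels.

Days are keyed by ``(year, day_of_year)`` where ``day_of_year`` is the index of
the calendar date in a *leap* year (1..366).  This makes the key a pure function
of (month, day): Feb 29 is day 60 in every leap year, Mar 1 is day 61 in every
year, and Dec 31 is day 366.  Matching "the same calendar day" across years is
then integer equality, and the Feb 29 climatology automatically draws on leap
years only (non-leap years never produce key 60).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def day_of_year_366(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Leap-calendar day-of-year (Feb 29 = 60, Mar 1 = 61 always)."""
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().astype(np.int64)
    shift = (~dates.is_leap_year) & (doy >= 60)
    doy[shift] += 1
    return doy


def seasonal_position(doy366: np.ndarray) -> np.ndarray:
    """Map the 366-day key onto a continuous 365-day seasonal coordinate.

    Feb 29 and Mar 1 share position 60; elsewhere the mapping is one-to-one.
    Used to evaluate smooth seasonal curves so that the same calendar day gets
    the same seasonal value in every year.
    """
    doy366 = np.asarray(doy366)
    return np.where(doy366 > 60, doy366 - 1, doy366)


def dates_for(year: int | np.ndarray, doy366: np.ndarray) -> pd.DatetimeIndex:
    """Reconstruct calendar dates from (year, day_of_year_366) keys."""
    year = np.broadcast_to(np.asarray(year), np.shape(doy366)).astype(int)
    doy366 = np.asarray(doy366).astype(int)
    # anchor in a reference leap year, then transplant the (month, day)
    ref = pd.Timestamp("2000-01-01") + pd.to_timedelta(doy366 - 1, unit="D")
    return pd.to_datetime(
        {"year": year, "month": ref.month, "day": ref.day}
    ).pipe(pd.DatetimeIndex)
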