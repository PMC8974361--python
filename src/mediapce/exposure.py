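"""Per-respondent lagged media-exposure windows.

Each respondent's exposure to a (source, valence) stream is the sum of that
stream's daily values over the L days *preceding* the interview date — the
interview day itself is excluded, because interviews happen during the day
and same-day coverage may postdate the interview; the exclusive window
preserves temporal order between coverage and response.  Everyone
interviewed on the same day shares the same exposure vector.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .series import DailySourceSeries

__all__ = ["window_sum", "windowed_frame", "build_exposure_matrix"]


def window_sum(series: DailySourceSeries, interview_date: dt.date, L: int) -> float:
    """Sum of the L days before ``interview_date`` (exclusive of it).

    Returns ``nan`` (missing) when the window extends before the series
    start or past its end — a partial window is not a valid exposure.
    """
    if L <= 0:
        raise ValueError("window length L must be positive")
    win_start = interview_date - dt.timedelta(days=L)
    win_end = interview_date - dt.timedelta(days=1)
    if win_start < series.start or win_end > series.end:
        return float("nan")
    i0 = (win_start - series.start).days
    return float(series.values[i0 : i0 + L].sum())


def windowed_frame(values: pd.DataFrame, L: int) -> pd.DataFrame:
    """L-day trailing sums (exclusive of the index day) of a daily frame.

    ``values`` is the aligned calendar frame (one row per day, NaN where a
    source is missing).  Any missing or absent day inside a window makes
    that window's sum missing, which is what ``min_periods=L`` plus NaN
    propagation delivers.
    """
    if L <= 0:
        raise ValueError("window length L must be positive")
    win = values.rolling(L, min_periods=L).sum()
    # mark windows that touched any masked day as missing
    win[values.isna().rolling(L, min_periods=1).max().astype(bool)] = np.nan
    return win.shift(1)


def build_exposure_matrix(
    respondents: pd.DataFrame,
    values: pd.DataFrame,
    L: int,
    date_col: str = "interview_date",
    id_col: str = "respondent_id",
) -> pd.DataFrame:
    """Attach L-day exposure sums to every respondent by interview date.

    Respondents sharing an interview date receive identical values for
    every (source, valence) column.  Output columns are suffixed ``_w{L}``.
    Missing windows (early dates, or masked source days) stay NaN and are
    deleted listwise only by models that use those columns.
    """
    win = windowed_frame(values, L)
    dates = pd.to_datetime(respondents[date_col])
    out_of_range = ~dates.isin(win.index)
    if out_of_range.any():
        bad = sorted(dates[out_of_range].dt.date.unique())
        raise ValueError(f"interview dates outside the analyzable range: {bad[:5]}")
    exp = win.loc[dates].reset_index(drop=True)
    exp.columns = [f"{c}_w{L}" for c in exp.columns]
    out = respondents[[id_col, date_col]].reset_index(drop=True)
    return pd.concat([out, exp], axis=1)
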