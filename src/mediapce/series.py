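"""Calendar-aligned daily valence series per media source.

Long-form and Twitter sources aggregate document contributions into daily
sums; YouTube is view-weighted: only videos clearing a total-view threshold
qualify, their views count toward the series only during each video's first
30 days, and the daily totals enter on a natural-log scale because view
counts spike by orders of magnitude when a popular video lands.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import doc_valence_contribution
from .records import MediaDocument, Valence, VideoRecord

__all__ = [
    "DailySourceSeries",
    "aggregate_daily",
    "qualify_videos",
    "youtube_daily_series",
    "align_calendar",
]


@dataclass
class DailySourceSeries:
    """Daily values of one (source, valence) stream over a contiguous range."""

    source: str
    valence: str
    start: dt.date
    end: dt.date
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_days = (self.end - self.start).days + 1
        if n_days < 1:
            raise ValueError("end date precedes start date")
        if len(self.values) != n_days:
            raise ValueError(
                f"expected {n_days} values for {self.start}..{self.end}, "
                f"got {len(self.values)}"
            )
        if np.any(self.values < 0):
            raise ValueError("series values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_pandas(self) -> pd.Series:
        idx = pd.date_range(self.start, self.end, freq="D")
        return pd.Series(self.values, index=idx, name=f"{self.source}_{self.valence}")


def aggregate_daily(
    docs: list[MediaDocument],
    source: str,
    valence: Valence,
    start: dt.date,
    end: dt.date,
) -> DailySourceSeries:
    """Sum per-document valence contributions into a zero-filled daily series."""
    n_days = (end - start).days + 1
    if n_days < 1:
        raise ValueError("end date precedes start date")
    values = np.zeros(n_days)
    side = 0 if valence == "anti" else 1
    for doc in docs:
        if doc.source != source:
            raise ValueError(f"document {doc.doc_id} is from source {doc.source!r}, expected {source!r}")
        if doc.source_type == "youtube":
            raise ValueError("youtube records do not aggregate by document")
        if not (start <= doc.date <= end):
            raise ValueError(
                f"document {doc.doc_id} dated {doc.date} falls outside {start}..{end}"
            )
        values[(doc.date - start).days] += doc_valence_contribution(doc)[side]
    return DailySourceSeries(source, valence, start, end, values)


def qualify_videos(
    videos: list[VideoRecord], min_views: int = 10_000, horizon: int = 180
) -> list[VideoRecord]:
    """Keep videos with *more than* ``min_views`` total views in the
    ``horizon`` days after publication.

    The window is the ``horizon`` days strictly after the publish date and
    the threshold is strict, so a video at exactly ``min_views`` is dropped.
    Lowering ``min_views`` can only grow the qualifying set.
    """
    if min_views < 0 or horizon <= 0:
        raise ValueError("min_views must be >= 0 and horizon positive")
    kept = []
    for vid in videos:
        total = vid.views_between(
            vid.publish_date + dt.timedelta(days=1),
            vid.publish_date + dt.timedelta(days=horizon),
        )
        if total > min_views:
            kept.append(vid)
    return kept


def youtube_daily_series(
    videos: list[VideoRecord],
    valence: Valence,
    start: dt.date,
    end: dt.date,
    first_days: int = 30,
) -> DailySourceSeries:
    """ln(1 + daily views) of matching-valence videos in their first 30 days.

    A view on calendar day ``d`` counts iff ``0 <= d - publish < first_days``
    (days 0..29 after publication).  Zero-view days map to ln(1) = 0, which
    is why the log transform is shifted by one.
    """
    n_days = (end - start).days + 1
    if n_days < 1:
        raise ValueError("end date precedes start date")
    raw = np.zeros(n_days)
    for vid in videos:
        if vid.valence != valence:
            continue
        for day, views in vid.daily_views.items():
            age = (day - vid.publish_date).days
            if 0 <= age < first_days and start <= day <= end:
                raw[(day - start).days] += views
    return DailySourceSeries("youtube", valence, start, end, np.log1p(raw))


def align_calendar(
    series: list[DailySourceSeries],
    start: dt.date,
    end: dt.date,
    availability: dict[str, tuple[dt.date, dt.date]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack series into one row per calendar day with a missingness mask.

    Days outside a source's availability window are *missing* (NaN, mask
    set); days inside availability but not covered by the input series are
    zero — "no coverage that day" and "the source was not being measured"
    are different states, and the distinction drives listwise deletion in
    the models downstream.

    Returns
    -------
    values : DataFrame indexed by day, one ``source_valence`` column each.
    mask : boolean DataFrame, True where the value is missing.
    """
    availability = availability or {}
    idx = pd.date_range(start, end, freq="D")
    seen: set[tuple[str, str]] = set()
    values = {}
    mask = {}
    for s in series:
        key = (s.source, s.valence)
        if key in seen:
            raise ValueError(f"duplicate series for {key}")
        seen.add(key)
        col = s.to_pandas().reindex(idx).fillna(0.0)
        m = pd.Series(False, index=idx)
        if s.source in availability:
            av_start, av_end = availability[s.source]
            out = (idx < pd.Timestamp(av_start)) | (idx > pd.Timestamp(av_end))
            m[out] = True
            col[out] = np.nan
        name = f"{s.source}_{s.valence}"
        values[name] = col
        mask[name] = m
    return pd.DataFrame(values, index=idx), pd.DataFrame(mask, index=idx)
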