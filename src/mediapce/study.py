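"""End-to-end study assembly: media stream -> exposures -> indices -> survey.

This stitches the stages together in the order the analysis requires:
daily series per (source, valence) are aligned on the calendar (YouTube is
only available from its later collection start), summed over the trailing
exposure window, aggregated into first-principal-component composite
indices per valence with negatively loading sources split out, and the
day-level standardized scores feed both the survey generator (as the true
exposures) and the outcome models.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import PCEIndex
from .exposure import windowed_frame
from .series import align_calendar, qualify_videos, youtube_daily_series
from .synthetic import VALENCES, GeneratorConfig, MediaStream, gen_media_stream, gen_survey

__all__ = [
    "StudyData",
    "assemble_day_scores",
    "simulate_study",
    "calibration_table",
    "exposure_matrix",
    "expected_weekly_views_per_person",
]


def expected_weekly_views_per_person(weekly_views: float, population: float) -> float:
    """Expected weekly video views per population member.

    The back-of-envelope audience-reach check: even attributing the entire
    weekly view volume of topic-relevant videos to the age group of
    interest, the expected per-person weekly exposure is this ratio — for
    tobacco videos against the U.S. 13-25 population, far below one view
    per week, too low for the video channel to move outcomes on its own.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if weekly_views < 0:
        raise ValueError("weekly view volume cannot be negative")
    return weekly_views / population


def _all_series(stream: MediaStream, include_youtube: bool = True):
    cfg = stream.config
    out = [stream.source_series(s.name, v) for s in cfg.sources for v in VALENCES]
    availability = {}
    if include_youtube:
        qualified = qualify_videos(
            stream.videos, cfg.youtube.min_views, cfg.youtube.view_horizon
        )
        for v in VALENCES:
            out.append(
                youtube_daily_series(qualified, v, cfg.start_date, cfg.end_date)
            )
        availability["youtube"] = (cfg.youtube.start_date, cfg.end_date)
    return out, availability


def assemble_day_scores(
    stream: MediaStream, window: int = 7
) -> tuple[pd.DataFrame, dict[str, PCEIndex]]:
    """Windowed exposures -> composite indices -> day-level score frame.

    For each valence, the composite is fit on unique day rows (everyone
    interviewed the same day shares exposures, so person rows would merely
    reweight days by interview counts) over the days where all candidate
    sources are observed.  Sources screened out for negative loadings —
    YouTube, at the default calibration — become standalone standardized
    variables, missing on days before their collection started.

    Returns the day-indexed frame with columns ``anti_index``,
    ``pro_index``, ``anti_youtube``, ``pro_youtube`` over survey days, and
    the fitted :class:`PCEIndex` per valence.
    """
    cfg = stream.config
    series, availability = _all_series(stream)
    values, _mask = align_calendar(series, cfg.start_date, cfg.end_date, availability)
    win = windowed_frame(values, window)
    survey_days = pd.date_range(cfg.survey_start, cfg.end_date, freq="D")
    win = win.loc[survey_days]

    scores = pd.DataFrame(index=survey_days)
    indices: dict[str, PCEIndex] = {}
    for v in VALENCES:
        cand_cols = [f"{s.name}_{v}" for s in cfg.sources] + [f"youtube_{v}"]
        complete = win[cand_cols].dropna()
        index = PCEIndex(screen_negative=True).fit(complete)
        indices[v] = index
        kept_cols = [c for c in cand_cols if c in index.included_sources_]
        kept = win[kept_cols]
        vals = np.full(len(win), np.nan)
        ok = ~kept.isna().any(axis=1)
        vals[ok.to_numpy()] = index.transform(kept.loc[ok])
        scores[f"{v}_index"] = vals
        # screened-out sources enter standalone, standardized over observed days
        yt = win[f"youtube_{v}"]
        scores[f"{v}_youtube"] = (yt - yt.mean()) / yt.std(ddof=1)
    return scores, indices


@dataclass
class StudyData:
    """One simulated study: stream, day scores, fitted indices, survey."""

    config: GeneratorConfig
    stream: MediaStream = field(repr=False)
    day_scores: pd.DataFrame = field(repr=False)
    indices: dict = field(repr=False)
    survey: pd.DataFrame = field(repr=False)
    followup: pd.DataFrame = field(repr=False)
    window: int = 7


def simulate_study(config: GeneratorConfig, window: int = 7) -> StudyData:
    """Generate media and survey and assemble analysis-ready tables."""
    stream = gen_media_stream(config)
    day_scores, indices = assemble_day_scores(stream, window=window)
    truth = day_scores[["anti_index", "pro_index"]].rename(
        columns={"anti_index": "anti", "pro_index": "pro"}
    )
    # should a composite ever retain a late-starting source, its index is
    # undefined on early days; those days simply field no interviews
    truth = truth.dropna()
    survey, followup = gen_survey(config, truth)
    return StudyData(
        config=config, stream=stream, day_scores=day_scores, indices=indices,
        survey=survey, followup=followup, window=window,
    )


def exposure_matrix(study: "StudyData") -> pd.DataFrame:
    """Per-respondent lagged window sums for every (source, valence).

    Everyone interviewed on a date shares a row's values; columns carry the
    window-length suffix (e.g. ``newspapers_anti_w7``).
    """
    from .exposure import build_exposure_matrix

    cfg = study.config
    series, availability = _all_series(study.stream)
    values, _ = align_calendar(series, cfg.start_date, cfg.end_date, availability)
    return build_exposure_matrix(study.survey, values, study.window)


def calibration_table(stream: MediaStream, window: int = 7) -> pd.DataFrame:
    """Simulated vs. target windowed means per source/valence.

    Targets are the calibrated weekly coverage levels (``daily_mean * 7``
    for document sources; raw first-30-day video views for YouTube, which
    is calibrated against its printed weekly view volume upstream).
    """
    cfg = stream.config
    series, availability = _all_series(stream)
    values, _ = align_calendar(series, cfg.start_date, cfg.end_date, availability)
    win = windowed_frame(values, window).loc[pd.date_range(cfg.survey_start, cfg.end_date)]
    rows = []
    for s in cfg.sources:
        for v in VALENCES:
            rows.append({
                "source": s.name, "valence": v,
                "simulated_mean": float(win[f"{s.name}_{v}"].mean()),
                "target": s.daily_mean[v] * window,
            })
    # youtube calibrates on raw views (its model variable is the logged series)
    raw = np.expm1(values[[f"youtube_{v}" for v in VALENCES]])
    raw_win = raw.rolling(window, min_periods=window).sum().shift(1)
    raw_win = raw_win.loc[pd.date_range(cfg.survey_start, cfg.end_date)]
    for v in VALENCES:
        rows.append({
            "source": "youtube", "valence": v,
            "simulated_mean": float(raw_win[f"youtube_{v}"].mean()),
            "target": cfg.youtube.weekly_views_target[v] / 7.0 * window,
        })
    out = pd.DataFrame(rows)
    out["rel_error"] = out["simulated_mean"] / out["target"] - 1.0
    return out
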