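"""Synthetic media streams and rolling cross-sectional survey.

The generator emulates the statistical structure the analysis pipeline
assumes, with injectable true effect sizes so every downstream stage can be
validated by parameter recovery:

* A latent daily "communication environment intensity" per valence follows
  an AR(1) process on the log scale — coverage is bursty, autocorrelated
  and non-negative.  Each long-form source's daily probability sum and
  Twitter's daily tweet count are mean-calibrated lognormal (respectively
  Poisson-lognormal) functions of that latent intensity plus source noise,
  so the five sources cohere the way a common underlying news agenda makes
  real sources cohere.
* YouTube is generated per video: heavy-tailed total views with a geometric
  daily decay, producing the extreme view spikes that motivate the log
  transform.  View scale couples weakly *negatively* to the latent
  intensity, reproducing the observed negative association between video
  views and the common factor of the other sources.
* The survey interviews ``n_per_day`` fresh respondents each day.  Smoking
  status is Bernoulli; the intention to smoke follows a logistic model in
  time, smoking status and the standardized exposure indices, with the
  interaction and all coefficients set on the log-odds scale in
  :class:`EffectBlock`.  Belief items are equicorrelated latent normals cut
  into four ordinal categories, with effects injected on the *observed*
  1-4 scale by numerically inverting the ordinal mean function, so the
  generator truth equals the regression estimand.

Identical seed and config give byte-identical output: every stage draws
from its own seed-derived substream.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .records import MediaDocument, Valence, VideoRecord
from .series import DailySourceSeries

__all__ = [
    "SourceSpec",
    "YouTubeSpec",
    "EffectBlock",
    "BeliefBlock",
    "FollowupBlock",
    "GeneratorConfig",
    "MediaStream",
    "gen_media_stream",
    "gen_survey",
]

VALENCES: tuple[Valence, ...] = ("anti", "pro")


class SourceSpec(BaseModel):
    """One long-form or Twitter source: calibrated level and factor structure.

    ``daily_mean`` is the expected daily valence mass (probability sum for
    long-form, tweet count for Twitter); ``loading`` and ``noise_sd`` act
    on the log scale, so ``loading**2 / (loading**2 + noise_sd**2)`` is the
    share of a source's daily log-variance carried by the common factor.
    """

    name: str
    type: Literal["longform", "twitter"]
    daily_mean: dict[str, float]
    loading: dict[str, float]
    noise_sd: dict[str, float]

    @model_validator(mode="after")
    def _positive(self) -> "SourceSpec":
        for v in VALENCES:
            if self.daily_mean.get(v, 1.0) <= 0:
                raise ValueError(f"{self.name}: daily_mean[{v}] must be positive")
            if self.noise_sd.get(v, 1.0) <= 0:
                raise ValueError(f"{self.name}: noise_sd[{v}] must be positive")
        return self


class YouTubeSpec(BaseModel):
    """Per-video view-process parameters for the YouTube-like source."""

    videos_per_day: float = 0.9
    log_views_mu: float = 8.4
    log_views_sd: float = 1.3
    decay: float = 0.88          # geometric daily share of remaining views
    span_days: int = 45          # views essentially exhausted after this
    latent_coupling: float = -0.8
    #: weekly raw first-30-day view volume the defaults are calibrated to
    weekly_views_target: dict[str, float] = {"anti": 79_773.0, "pro": 72_317.0}
    start_date: dt.date = dt.date(2014, 7, 30)
    min_views: int = 10_000
    view_horizon: int = 180


def _default_sources() -> list[SourceSpec]:
    # daily_mean = printed 7-day mean / 7 for each source and valence
    mk = lambda name, typ, anti_w, pro_w: SourceSpec(
        name=name,
        type=typ,
        daily_mean={"anti": anti_w / 7.0, "pro": pro_w / 7.0},
        loading={"anti": 0.40, "pro": 0.40},
        noise_sd={"anti": 0.70, "pro": 0.67},
    )
    return [
        mk("broadcast", "longform", 0.20, 0.05),
        mk("ap", "longform", 0.93, 0.05),
        mk("newspapers", "longform", 3.62, 0.57),
        mk("web", "longform", 5.31, 1.07),
        mk("twitter", "twitter", 12_948.0, 21_336.0),
    ]


class EffectBlock(BaseModel):
    """True intention-model coefficients on the log-odds scale."""

    intercept: float = float(np.log(0.28))
    beta_smoker: float = float(np.log(14.21))
    beta_anti: float = float(np.log(0.95))
    beta_pro: float = float(np.log(1.02))
    beta_interaction: float = float(np.log(0.88))
    beta_time: float = float(np.log(0.92))


class BeliefBlock(BaseModel):
    """Belief-item generator: equicorrelated latent normal cut to 1-4.

    ``category_probs`` fix the marginal distribution (defaults give an item
    mean near 3.0); effects are targets on the observed scale.
    """

    n_items: int = 12
    latent_corr: float = 0.45
    category_probs: tuple[float, float, float, float] = (0.047, 0.196, 0.464, 0.293)
    effect_smoker: float = -0.409
    effect_time: float = 0.017
    effect_anti: float = -0.004
    effect_pro: float = 0.002
    n_reverse: int = 2

    @model_validator(mode="after")
    def _probs(self) -> "BeliefBlock":
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        if not 0 <= self.latent_corr < 1:
            raise ValueError("latent_corr must be in [0, 1)")
        return self


class FollowupBlock(BaseModel):
    """Six-month recontact behavior conditional on baseline intention."""

    rate: float = 0.38
    p_smoke_given_intent: float = 0.48
    p_smoke_given_none: float = 0.021
    p_quit_attempt_given_quit_intent: float = 0.875
    p_quit_attempt_given_none: float = 0.25

    @model_validator(mode="after")
    def _rates(self) -> "FollowupBlock":
        for v in (self.rate, self.p_smoke_given_intent, self.p_smoke_given_none,
                  self.p_quit_attempt_given_quit_intent, self.p_quit_attempt_given_none):
            if not 0 <= v <= 1:
                raise ValueError("follow-up probabilities must be in [0, 1]")
        return self


class GeneratorConfig(BaseModel):
    """Full study design: dates, sources, survey, and true effects."""

    start_date: dt.date = dt.date(2014, 5, 18)
    end_date: dt.date = dt.date(2017, 6, 30)
    survey_lead_days: int = 28
    n_per_day: int = Field(default=10, ge=1)
    latent_ar_rho: float = 0.6
    smoker_prevalence: float = Field(default=0.12, ge=0.0, le=1.0)
    weight_log_sd: float = Field(default=0.3, ge=0.0)
    sources: list[SourceSpec] = Field(default_factory=_default_sources)
    youtube: YouTubeSpec = Field(default_factory=YouTubeSpec)
    effects: EffectBlock = Field(default_factory=EffectBlock)
    beliefs: BeliefBlock = Field(default_factory=BeliefBlock)
    followup: FollowupBlock = Field(default_factory=FollowupBlock)
    seed: int = 0

    @model_validator(mode="after")
    def _dates(self) -> "GeneratorConfig":
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if abs(self.latent_ar_rho) >= 1:
            raise ValueError("|latent_ar_rho| must be < 1")
        n_days = (self.end_date - self.start_date).days + 1
        if self.survey_lead_days >= n_days:
            raise ValueError("survey lead exceeds the study period")
        return self

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def survey_start(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.survey_lead_days)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# substream ids (kept stable so artifacts are reproducible per stage)
_LATENT, _SOURCE, _YOUTUBE, _DOCS, _SURVEY = 11, 12, 13, 14, 15


def _rng(config: GeneratorConfig, *ids: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *ids])


def _latent(config: GeneratorConfig) -> pd.DataFrame:
    """Stationary AR(1) latent intensity per valence, unit marginal variance."""
    n, rho = config.n_days, config.latent_ar_rho
    out = {}
    for vi, v in enumerate(VALENCES):
        rng = _rng(config, _LATENT, vi)
        e = rng.standard_normal(n)
        z = np.empty(n)
        z[0] = e[0]
        c = np.sqrt(1 - rho**2)
        for t in range(1, n):
            z[t] = rho * z[t - 1] + c * e[t]
        out[v] = z
    idx = pd.date_range(config.start_date, config.end_date, freq="D")
    return pd.DataFrame(out, index=idx)


@dataclass
class MediaStream:
    """Generated media: daily series, video records, on-demand documents."""

    config: GeneratorConfig
    latent: pd.DataFrame = field(repr=False)
    series: pd.DataFrame = field(repr=False)  # source_valence daily values
    videos: list[VideoRecord] = field(repr=False, default_factory=list)

    def source_series(self, source: str, valence: Valence) -> DailySourceSeries:
        col = self.series[f"{source}_{valence}"]
        return DailySourceSeries(
            source, valence, self.config.start_date, self.config.end_date,
            col.to_numpy(),
        )

    def documents_for(self, source: str, start: dt.date, end: dt.date) -> list[MediaDocument]:
        """Materialize the documents behind the daily series for a date range.

        Deterministic per (source, day): the same range yields the same
        records regardless of call order.  Long-form probabilities are a
        Dirichlet split of the day's series value, so aggregating the
        documents reproduces the series exactly; Twitter materializes one
        flagged record per counted tweet.
        """
        spec = next((s for s in self.config.sources if s.name == source), None)
        if spec is None:
            raise ValueError(f"unknown source {source!r}")
        si = self.config.sources.index(spec)
        docs: list[MediaDocument] = []
        day = start
        while day <= end:
            di = (day - self.config.start_date).days
            if di < 0 or di >= self.config.n_days:
                raise ValueError(f"{day} outside the configured period")
            rng = _rng(self.config, _DOCS, si, di)
            for v in VALENCES:
                target = float(self.series[f"{source}_{v}"].iloc[di])
                p_pair = (lambda p: (p, 0.0)) if v == "anti" else (lambda p: (0.0, p))
                if spec.type == "twitter":
                    for j in range(int(round(target))):
                        pa, pp = p_pair(1.0)
                        docs.append(MediaDocument(
                            doc_id=f"{source}-{day.isoformat()}-{v}-{j}",
                            source=source, source_type="twitter", date=day,
                            p_anti=pa, p_pro=pp,
                        ))
                    continue
                if target <= 0:
                    continue
                n = max(1, int(rng.poisson(target / 0.35)), int(np.ceil(target / 0.95)))
                probs = target * rng.dirichlet(np.full(n, 8.0))
                if probs.max() > 1.0:
                    probs = np.full(n, target / n)
                for j, p in enumerate(probs):
                    pa, pp = p_pair(float(p))
                    label = v if p >= 0.5 else "not_applicable"
                    votes = rng.multinomial(
                        9, [0.8 if lab == label else 0.05
                            for lab in ("anti", "pro", "mixed", "not_applicable")]
                    )
                    docs.append(MediaDocument(
                        doc_id=f"{source}-{day.isoformat()}-{v}-{j}",
                        source=source, source_type="longform", date=day,
                        p_anti=pa, p_pro=pp,
                        coder_votes={
                            lab: int(c) for lab, c in zip(
                                ("anti", "pro", "mixed", "not_applicable"), votes)
                        },
                    ))
            # passing-mention texts: relevant but not substantially about the
            # topic; they carry no valence mass into the series
            if spec.type == "longform":
                for j in range(rng.poisson(0.3)):
                    docs.append(MediaDocument(
                        doc_id=f"{source}-{day.isoformat()}-pass-{j}",
                        source=source, source_type="longform", date=day,
                        p_anti=float(rng.uniform(0, 0.4)),
                        p_pro=float(rng.uniform(0, 0.2)),
                        more_than_passing=False,
                    ))
            day += dt.timedelta(days=1)
        return docs


def gen_media_stream(config: GeneratorConfig) -> MediaStream:
    """Generate daily media series and video records for the whole period."""
    latent = _latent(config)
    n = config.n_days
    cols = {}
    for si, spec in enumerate(config.sources):
        for vi, v in enumerate(VALENCES):
            rng = _rng(config, _SOURCE, si, vi)
            a = spec.loading[v]
            s = spec.noise_sd[v]
            m = spec.daily_mean[v]
            log_part = a * latent[v].to_numpy() + s * rng.standard_normal(n)
            value = m * np.exp(log_part - 0.5 * (a**2 + s**2))
            if spec.type == "twitter":
                value = rng.poisson(value).astype(float)
            cols[f"{spec.name}_{v}"] = value
    series = pd.DataFrame(cols, index=latent.index)

    videos: list[VideoRecord] = []
    yt = config.youtube
    shares_full = yt.decay ** np.arange(yt.span_days)
    shares_full = shares_full / shares_full.sum()
    for vi, v in enumerate(VALENCES):
        rng = _rng(config, _YOUTUBE, vi)
        z = latent[v].to_numpy()
        counts = rng.poisson(yt.videos_per_day, size=n)
        for di in np.flatnonzero(counts):
            day = config.start_date + dt.timedelta(days=int(di))
            for j in range(counts[di]):
                total = np.exp(
                    yt.log_views_mu
                    + yt.log_views_sd * rng.standard_normal()
                    + yt.latent_coupling * z[di]
                )
                daily = rng.multinomial(int(round(total)), shares_full)
                views = {
                    day + dt.timedelta(days=int(k)): int(c)
                    for k, c in enumerate(daily) if c > 0
                }
                videos.append(VideoRecord(
                    video_id=f"yt-{v}-{day.isoformat()}-{j}",
                    publish_date=day, valence=v, daily_views=views,
                ))
    return MediaStream(config=config, latent=latent, series=series, videos=videos)


# ---------------------------------------------------------------------------
# survey


def _belief_thresholds(block: BeliefBlock) -> np.ndarray:
    return norm.ppf(np.cumsum(block.category_probs[:-1]))


def _ordinal_mean(delta: float, tau: np.ndarray) -> float:
    """Expected 1-4 item value when the unit-variance latent shifts by delta."""
    return float(1.0 + norm.cdf(delta - tau).sum())


def _invert_effect(target: float, tau: np.ndarray) -> float:
    """Latent shift whose expected observed-scale effect equals ``target``."""
    if target == 0.0:
        return 0.0
    base = _ordinal_mean(0.0, tau)
    f = lambda d: _ordinal_mean(d, tau) - base - target
    return float(brentq(f, -6.0, 6.0, xtol=1e-12))


def gen_survey(
    config: GeneratorConfig, exposures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the rolling cross-sectional survey given day-level exposures.

    ``exposures`` is indexed by interview date and must provide complete
    ``anti`` and ``pro`` standardized index values for every interview day
    (a missing exposure is an error, matching the exogenous-measurement
    design: respondents inherit their day's scores).

    Returns ``(survey, followup)``; the follow-up subtable covers the
    recontacted subsample with the behavior outcome appropriate to baseline
    smoking status.
    """
    for col in ("anti", "pro"):
        if col not in exposures.columns:
            raise ValueError(f"exposures must contain column {col!r}")
        if exposures[col].isna().any():
            bad = exposures.index[exposures[col].isna()][:3]
            raise ValueError(f"missing {col} exposure for interview dates {list(bad)}")
    rng = _rng(config, _SURVEY)
    dates = pd.to_datetime(exposures.index)
    n_days = len(dates)
    npd = config.n_per_day
    n = n_days * npd

    day_idx = np.repeat(np.arange(n_days), npd)
    interview = dates[day_idx]
    t_days = (interview - interview.min()).days.to_numpy(dtype=float)
    t_std = (t_days - t_days.mean()) / t_days.std(ddof=1)
    A = exposures["anti"].to_numpy()[day_idx]
    P = exposures["pro"].to_numpy()[day_idx]

    eff = config.effects
    S = (rng.random(n) < config.smoker_prevalence).astype(int)
    eta = (
        eff.intercept + eff.beta_smoker * S + eff.beta_anti * A + eff.beta_pro * P
        + eff.beta_interaction * S * A + eff.beta_time * t_std
    )
    intention = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    # raw smoking-history items consistent with the established-smoker rule
    ever = np.where(S == 1, 1, (rng.random(n) < 0.35).astype(int))
    hundred = np.where(S == 1, 1, np.where(ever == 1, (rng.random(n) < 0.1), 0)).astype(int)
    days30 = np.where(
        S == 1, rng.integers(1, 31, size=n),
        np.where((ever == 1) & (hundred == 1), 0, 0),
    )
    # 4-level intention answers consistent with the binary coding
    init_open = np.array(["probably will not", "probably will", "definitely will"])
    init_ans = np.where(
        intention == 1, init_open[rng.integers(0, 3, size=n)], "definitely will not"
    )
    quit_open = np.array(["definitely will not", "probably will not", "probably will"])
    quit_ans = np.where(
        intention == 1, quit_open[rng.integers(0, 3, size=n)], "definitely will"
    )
    init_ans = np.where(S == 1, "", init_ans)
    quit_ans = np.where(S == 0, "", quit_ans)

    # belief items: equicorrelated latent normal, observed-scale effects
    bb = config.beliefs
    tau = _belief_thresholds(bb)
    shift = (
        _invert_effect(bb.effect_smoker, tau) * S
        + _invert_effect(bb.effect_time, tau) * t_std
        + _invert_effect(bb.effect_anti, tau) * A
        + _invert_effect(bb.effect_pro, tau) * P
    )
    common = rng.standard_normal(n)
    uniq = rng.standard_normal((n, bb.n_items))
    latent = (
        shift[:, None]
        + np.sqrt(bb.latent_corr) * common[:, None]
        + np.sqrt(1 - bb.latent_corr) * uniq
    )
    items = 1 + (latent[:, :, None] > tau[None, None, :]).sum(axis=2)
    # last n_reverse items are stored reverse-scored (agreement = pro-smoking)
    stored = items.copy()
    stored[:, bb.n_items - bb.n_reverse:] = 5 - stored[:, bb.n_items - bb.n_reverse:]

    weights = rng.lognormal(0.0, config.weight_log_sd, size=n) if config.weight_log_sd > 0 else np.ones(n)
    weights = weights / weights.mean()

    survey = pd.DataFrame({
        "respondent_id": [f"r{i:06d}" for i in range(n)],
        "interview_date": interview.date,
        "weight": weights,
        "ever_tried": ever,
        "smoked_100": hundred,
        "days_smoked_30": days30,
        "established_smoker": S,
        "initiation_answer": init_ans,
        "quit_answer": quit_ans,
        "intention": intention,
    })
    for j in range(bb.n_items):
        survey[f"belief_{j+1}"] = stored[:, j]

    recontact = rng.random(n) < config.followup.rate
    fb = config.followup
    smoked = rng.random(n) < np.where(intention == 1, fb.p_smoke_given_intent,
                                      fb.p_smoke_given_none)
    # for smokers intention==0 means "definitely will quit"
    quit_attempt = rng.random(n) < np.where(
        intention == 0, fb.p_quit_attempt_given_quit_intent, fb.p_quit_attempt_given_none
    )
    followup = pd.DataFrame({
        "respondent_id": survey.loc[recontact, "respondent_id"],
        "established_smoker": S[recontact],
        "intention": intention[recontact],
        "smoked_30day": np.where(S[recontact] == 0, smoked[recontact].astype(float), np.nan),
        "quit_attempt": np.where(S[recontact] == 1, quit_attempt[recontact].astype(float), np.nan),
    }).reset_index(drop=True)
    return survey, followup
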