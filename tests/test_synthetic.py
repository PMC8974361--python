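"""Generator contracts: reproducibility, calibration structure, recovery."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from mediapce.models import (
    cronbach_alpha,
    derive_established_smoker,
    derive_intention,
    fit_weighted_logistic,
)
from mediapce.series import aggregate_daily
from mediapce.synthetic import (
    EffectBlock,
    GeneratorConfig,
    SourceSpec,
    gen_media_stream,
    gen_survey,
)

from .conftest import small_config


class TestConfigValidation:
    def test_dates_must_be_ordered(self):
        with pytest.raises(ValueError):
            GeneratorConfig(start_date=dt.date(2015, 1, 1), end_date=dt.date(2014, 1, 1))

    def test_ar_coefficient_bounded(self):
        with pytest.raises(ValueError):
            small_config(latent_ar_rho=1.0)

    def test_nonpositive_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            SourceSpec(
                name="x", type="longform",
                daily_mean={"anti": 1, "pro": 1},
                loading={"anti": 0.4, "pro": 0.4},
                noise_sd={"anti": 0.0, "pro": 0.5},
            )

    def test_n_per_day_at_least_one(self):
        with pytest.raises(ValueError):
            small_config(n_per_day=0)

    def test_config_hash_stable_and_sensitive(self):
        a, b = small_config(seed=1), small_config(seed=1)
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != small_config(seed=2).config_hash()


class TestReproducibility:
    def test_same_seed_identical_different_seed_differs(self):
        s1 = gen_media_stream(small_config(seed=5))
        s2 = gen_media_stream(small_config(seed=5))
        s3 = gen_media_stream(small_config(seed=6))
        pd.testing.assert_frame_equal(s1.series, s2.series)
        assert s1.videos == s2.videos
        assert not s1.series.equals(s3.series)

    def test_survey_reproducible(self, small_study):
        from mediapce.study import simulate_study

        again = simulate_study(small_config(seed=7))
        pd.testing.assert_frame_equal(small_study.survey, again.survey)
        pd.testing.assert_frame_equal(small_study.followup, again.followup)

    def test_document_materialization_order_independent(self):
        stream = gen_media_stream(small_config(seed=3))
        d0 = stream.config.start_date
        d5 = d0 + dt.timedelta(days=5)
        whole = stream.documents_for("ap", d0, d5)
        tail_first = stream.documents_for("ap", d5, d5)
        assert [d for d in whole if d.date == d5] == tail_first


class TestStreamStructure:
    def test_document_aggregation_reproduces_series(self):
        stream = gen_media_stream(small_config(seed=11))
        cfg = stream.config
        d0 = cfg.start_date
        d1 = d0 + dt.timedelta(days=9)
        for source in ("newspapers", "twitter"):
            docs = stream.documents_for(source, d0, d1)
            for valence in ("anti", "pro"):
                agg = aggregate_daily(docs, source, valence, d0, d1)
                np.testing.assert_allclose(
                    agg.values,
                    stream.series[f"{source}_{valence}"].iloc[:10].to_numpy(),
                    atol=1e-9,
                )

    def test_video_views_start_at_publication(self):
        stream = gen_media_stream(small_config(seed=11))
        assert stream.videos, "default calibration should publish videos"
        for vid in stream.videos[:50]:
            assert all(d >= vid.publish_date for d in vid.daily_views)

    def test_series_nonnegative(self):
        stream = gen_media_stream(small_config(seed=11))
        assert (stream.series.to_numpy() >= 0).all()


class TestSurvey:
    def _exposures(self, config, rng=None):
        days = pd.date_range(config.survey_start, config.end_date, freq="D")
        rng = rng or np.random.default_rng(0)
        a = rng.standard_normal(len(days))
        p = rng.standard_normal(len(days))
        return pd.DataFrame({"anti": a, "pro": p}, index=days)

    def test_margins_match_design(self, small_study):
        survey = small_study.survey
        assert survey.established_smoker.mean() == pytest.approx(0.12, abs=0.03)
        assert survey.intention.mean() == pytest.approx(0.29, abs=0.04)
        assert survey.weight.mean() == pytest.approx(1.0, abs=1e-9)
        assert len(survey) == 200 * 10

    def test_raw_items_consistent_with_derivations(self, small_study):
        s = small_study.survey
        np.testing.assert_array_equal(
            derive_established_smoker(s.ever_tried, s.smoked_100, s.days_smoked_30),
            s.established_smoker,
        )
        nonsmokers = s[s.established_smoker == 0]
        smokers = s[s.established_smoker == 1]
        got = derive_intention(
            np.r_[np.zeros(len(nonsmokers)), np.ones(len(smokers))],
            np.r_[nonsmokers.initiation_answer, ["definitely will not"] * len(smokers)],
            np.r_[["definitely will"] * len(nonsmokers), smokers.quit_answer],
        )
        np.testing.assert_array_equal(got, np.r_[nonsmokers.intention, smokers.intention])

    def test_belief_items_ordinal_and_consistent(self, small_study):
        items = small_study.survey[[f"belief_{i}" for i in range(1, 13)]]
        assert items.min().min() >= 1 and items.max().max() <= 4
        oriented = items.copy()
        for c in ("belief_11", "belief_12"):
            oriented[c] = 5 - oriented[c]
        alpha = cronbach_alpha(oriented.to_numpy())
        assert 0.78 <= alpha <= 0.93  # calibrated near the 0.87 target

    def test_missing_exposure_is_an_error(self):
        cfg = small_config(seed=1)
        exp = self._exposures(cfg)
        exp.iloc[3, 0] = np.nan
        with pytest.raises(ValueError, match="missing anti exposure"):
            gen_survey(cfg, exp)

    def test_followup_rate_zero_gives_empty_subtable(self):
        cfg = small_config(seed=1)
        cfg = cfg.model_copy(update={"followup": cfg.followup.model_copy(update={"rate": 0.0})})
        _, followup = gen_survey(cfg, self._exposures(cfg))
        assert followup.empty

    def test_followup_behavior_tracks_intention(self, small_study):
        fu = small_study.followup
        assert len(fu) == pytest.approx(0.38 * 2000, rel=0.15)
        non = fu[fu.established_smoker == 0]
        p1 = non.loc[non.intention == 1, "smoked_30day"].mean()
        p0 = non.loc[non.intention == 0, "smoked_30day"].mean()
        assert p1 > p0  # intenders smoke more at follow-up

    def test_null_anti_effect_recovers_unit_or(self):
        cfg = small_config(
            seed=9,
            n_per_day=25,
            effects=EffectBlock(beta_anti=0.0, beta_pro=0.0, beta_interaction=0.0),
        )
        exp = self._exposures(cfg)
        survey, _ = gen_survey(cfg, exp)
        X = pd.DataFrame({
            "established_smoker": survey.established_smoker.astype(float),
            "anti": exp.loc[pd.to_datetime(survey.interview_date), "anti"].to_numpy(),
        })
        res = fit_weighted_logistic(
            survey.intention, X, weights=survey.weight,
            clusters=survey.interview_date,
        )
        f = res.to_frame()
        z = f.loc["anti", "coef"] / f.loc["anti", "se"]
        assert abs(z) < 3.0  # unit OR within Monte-Carlo error
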