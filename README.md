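# mediapce

Does day-to-day variation in what the media say about a health behavior
predict what people intend to do about it?  `mediapce` implements the full
analysis chain for linking **exogenously measured media coverage** — daily,
valence-coded content from several source categories (newspapers, wire,
broadcast transcripts, web blogs, Twitter, YouTube) — to outcomes measured
in a **rolling cross-sectional survey** (roughly ten fresh respondents
interviewed every day for three years).  Because content is measured from
archives rather than self-report, exposure and outcome share no common
method, which is the core of the design's causal argument.

The package covers every stage:

1. **Content coding** — crowd-coder training-set eligibility (a text
   qualifies when ≥ 70% of coders agree), re-assignment of the five-way
   scheme (anti / pro / mixed / not-applicable / irrelevant) to two binary
   codes, precision/recall validation against gold labels, and per-document
   contributions to daily series (probability sums for long-form text,
   counts for tweets, with passing mentions excluded).
2. **Daily series** — calendar-aligned per-source daily valence values;
   YouTube is view-weighted: videos qualify with more than 10,000 views in
   the 180 days after publication, views count only during each video's
   first 30 days, and daily totals enter as ln(1 + views).
3. **Exposure** — trailing 7-day (or 28-day) window sums assigned to every
   respondent by interview date, with the interview day excluded so
   coverage always precedes response.
4. **Composite index** — sources are treated as indicators of one
   underlying communication environment: the index weights each source by
   its loading on the first principal component of the inter-source
   correlation matrix, with reliability

   θ = (p / (p − 1)) · (1 − 1/λ₁),

   where λ₁ is the leading eigenvalue over p sources.  Sources whose
   oriented loading is negative (the YouTube view stream, in practice) are
   split out as standalone standardized variables.
5. **Models** — weighted logistic regression of smoking intentions (and
   weighted OLS for a 12-item belief scale, α-checked) on the standardized
   indices, smoking status, time, and a smoker × anti-index interaction;
   inference is clustered on interview date via the sandwich estimator
   with the G/(G − 1) small-sample factor.  A Gauss–Hermite random-intercept
   logit provides the multilevel sensitivity check, and delta-method
   adjusted-prediction curves describe the interaction.
6. **Synthetic data** — a calibrated generator (latent AR(1) daily
   intensity per valence, lognormal source noise, per-video heavy-tailed
   view trajectories, a logistic survey model with injectable true odds
   ratios) so that every stage is testable by parameter recovery without
   any external data.

## Worked example

```python
from mediapce import GeneratorConfig, simulate_study
from mediapce.pipeline import fit_named_model

study = simulate_study(GeneratorConfig(seed=42))
anti = study.indices["anti"]
print(anti.weights_.round(3), anti.theta_)
print(fit_named_model(study, "intentions-interaction").to_frame().round(3))
```

prints (abridged):

```
anti composite: included = [broadcast, ap, newspapers, web, twitter] (anti)
weights = [0.441, 0.465, 0.429, 0.413, 0.486]
lambda1 = 2.464   theta = 0.743
excluded = [('youtube_anti', -0.112)]
                    odds_ratio  or_ci_low  or_ci_high      p
const                    0.272      0.258       0.287  0.000
time_std                 0.907      0.864       0.954  0.000
established_smoker      15.117     12.996      17.584  0.000
anti_index               0.950      0.898       1.004  0.067
pro_index                1.029      0.976       1.084  0.288
anti_youtube             1.004      0.961       1.049  0.845
pro_youtube              1.033      0.983       1.085  0.200
smoker_x_anti            1.030      0.896       1.184  0.677
n = 10600  clusters = 1060
```

Reading it: the five text/tweet sources cohere into a single factor
(θ = 0.74 here — the weekly agreement of independent sources is the
evidence that they index one underlying communication environment), the
video stream loads negatively and is screened out, and a one-SD increase
in the week's anti-tobacco coverage multiplies the odds of being open to
smoking by about 0.95, with established smoking itself the dominant
predictor.  At a single simulated study of this size the anti-coverage
and interaction terms sit at the edge of detectability — exactly the
power situation the design implies; the recovery tests confirm the
estimator is centered on the injected truth.

A CLI mirrors the stages (`mediapce simulate | code | aggregate |
youtube-series | validate | fit | report`); `mediapce report --seed 1
--out run/` writes the complete artifact bundle (tidy series CSV, exposure
scores, index JSON, model JSON, prediction grid, manifest with config
hash) and is byte-reproducible for a fixed config and seed.

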