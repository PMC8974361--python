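# Methods

## The estimand and the design

The analysis asks whether short-run variation in valenced media coverage
of smoking predicts daily variation in young people's intentions to smoke.
Exposure is *exogenous*: it is measured from media archives, not from
respondents, so the predictor and outcome share no common method variance.
Time (the interview date) is the analytic unit for exposure: everyone
interviewed on a day is assigned the same coverage scores, computed from
the 7 days (28 in sensitivity analyses) strictly before the interview.
The interview day itself is excluded from the window because interviews
happen during the day and same-day coverage may postdate the response;
the exclusive window preserves temporal order, which carries the causal
argument.

Outcomes are a binary openness-to-smoking indicator (nonsmokers anything
but "definitely will not" initiate; established smokers anything but
"definitely will" quit) and a 12-item anti-smoking belief scale (1–4,
two items reverse-scored, averaged).  An established smoker has ever
tried smoking, smoked 100+ lifetime cigarettes, and smoked on at least
one of the past 30 days.

## Daily series and exposure conventions

- Long-form sources contribute the day's sum of classifier probabilities
  of being anti (pro); only texts where the topic is more than a passing
  mention carry valence.  Twitter contributes daily counts of binary-coded
  tweets, every relevant tweet counting as a substantial mention.
- YouTube contributes ln(1 + daily views) of qualified videos.  Committed
  conventions where the rules needed sharpening: "first 30 days" means
  post-publication ages 0–29 inclusive; the qualification window is the
  180 days strictly after publication with a strict "> 10,000 views"
  threshold; the shifted log keeps zero-view days defined (ln 1 = 0).
  Views are attributed to the calendar day they occur, not lumped onto the
  publish day, since the daily volume is what indexes when the topic was
  prominent.
- "No coverage" and "not measured" are distinct: days inside a source's
  collection period with no documents are zeros; days outside it (the
  video stream starts ~10 weeks after the text streams) are missing, and
  any exposure window touching a missing day is missing.  Missing windows
  are deleted listwise only in models that include that source's terms.

## Composite index and reliability

Sources are noisy indicators of one underlying communication environment,
so per-valence exposures are aggregated by the first principal component
of the inter-source **correlation** matrix (correlation, not covariance:
daily newspaper probability sums sit near 4 while tweet counts are in the
thousands).  The component is fit on unique day-window rows rather than
person rows — respondents sharing a date share exposures, so person rows
would only reweight days by interview counts.  The eigenvector sign is
oriented so most loadings are positive (tie broken on the first source).
Reliability is θ = (p/(p−1))(1 − 1/λ₁).  A source with a strictly
negative oriented loading does not covary with the common factor; it is
excluded, the component refit on the remainder, and the excluded stream
enters models as its own standardized variable.  The composite score is
the standardized weighted sum of standardized columns (mean 0, SD 1 on
the fitting sample), invariant to affine rescaling of any input.

## Models and inference

The intention model is a logistic regression on standardized time,
established-smoker status, the anti and pro composite indices, the two
standalone video terms, and optionally smoker × anti-index.  Survey
weights (taken as input; their construction is out of scope) enter the
likelihood as importance weights, leaving coefficients invariant to
rescaling all weights.  Estimation is iteratively reweighted least
squares with step-halving, converged when the largest score component
falls below 1e−8 (at most 100 iterations); perfect separation is detected
and raised rather than reported as a finite estimate.  Inference clusters
on interview date: sandwich covariance with cluster-summed scores and the
G/(G−1) factor (with G ≈ 1,100 the choice among small-sample factors is
immaterial, but it must be fixed; statsmodels' OLS convention additionally
applies (n−1)/(n−k), which this package does not).  The belief model is
weighted least squares with the same sandwich.  The multilevel
sensitivity model integrates a normal per-date intercept out of the
likelihood with 15-node Gauss–Hermite quadrature (the marginal
log-likelihood moves by < 1e−4 when nodes are doubled at convergence) and
maximizes by L-BFGS-B with σ bounded at zero.  Adjusted predictions fix
covariates at weighted sample means, recompute product terms on the grid,
and propagate the cluster-robust covariance by the delta method on the
probability scale.  The intention-to-behavior validity check is a
two-sided unconditional two-proportion z-test (no particular test is
canonical here; the contrast is far from marginal either way).

## The synthetic-data generator

The generator's defaults *are* the study conditions; they are fixed, not
tuning knobs.

- **Latent intensity.**  Per valence, a stationary AR(1) process
  (ρ = 0.6) on the log scale drives all text/tweet sources: coverage is
  bursty, autocorrelated, and non-negative.  Each source's daily value is
  `mean × exp(a·z + s·ε − (a² + s²)/2)` — mean-preserving lognormal with
  factor loading `a` and idiosyncratic log-noise `s`; Twitter counts add
  a Poisson layer.  Daily means are the printed weekly per-source
  coverage levels divided by 7.  Loadings (0.40) and noise SDs (0.70
  anti, 0.67 pro) were calibrated once, by simulation at the design
  scale, so the five-source 7-day θ lands near the published 0.77/0.79;
  they were frozen before the acceptance checks were written.  The
  day-level variance decomposition is otherwise a free choice — no
  day-level moments beyond weekly means are published.
- **Videos.**  Per valence about 0.9 videos/day; total views are
  heavy-tailed lognormal (median e^8.4 ≈ 4,400, log-SD 1.3 — most videos
  fail qualification, a few spike to millions, reproducing the view
  spikes that motivate the log transform), allocated across 45 days by a
  geometric-decay multinomial.  View scale couples *negatively* (−0.8 on
  the log scale) to the latent intensity: a truly independent stream
  would make the sign of its sample loading a coin flip, whereas the
  empirical finding this emulates is a reliably negative association, so
  the generator reproduces that sign.  The weekly view volume is
  calibrated to the printed ~80k/72k.
- **Documents.**  The daily series is the primitive; document records are
  materialized on demand from per-(source, day) substreams: long-form
  probabilities are a Dirichlet split of the day's mass (so aggregation
  reproduces the series exactly), plus passing-mention texts carrying no
  valence; tweets materialize one flagged record per count.  Coder votes
  are multinomial around the true label.  Full-scale tweet volumes
  (~5,000/day) make eager materialization pointless; short ranges
  exercise the document path in tests.
- **Survey.**  Media run 2014-05-18 to 2017-06-30 (1,140 days); interviews
  start 28 days in so both window lengths are complete — 1,112 interview
  days at 10/day (≈ 11,100 respondents, matching the published design
  size).  The video stream starts 2014-07-30, which induces ≈ 520
  listwise-dropped cases in video-term models (the published analysis
  loses ≈ 450 the same way).  Smoking status is Bernoulli(0.12); the
  intention follows the logistic model with true odds ratios defaulting
  to the published estimates (smoker 14.21, anti 0.95, pro 1.02,
  interaction 0.88, time 0.92, constant 0.28) — implied margins: 22%
  nonsmoker intention, 80% smoker non-quit intention, 29% overall.
  Weights are i.i.d. lognormal(0, 0.3) normalized to mean 1 (raking is
  out of scope).  Follow-up recontacts 38% and draws behavior so that
  intention predicts it (2.1%/48% smoking among nonsmoker
  non-intenders/intenders; 87.5%/25% quit attempts among smokers by quit
  intention).
- **Belief items.**  Equicorrelated latent normals (r = 0.45) cut into
  four categories (marginals chosen for an item mean near 3.0).  Because
  ordinal cutting attenuates latent effects, covariate effects are
  injected on the *observed* 1–4 scale by numerically inverting the
  ordinal mean function (Brent root-finding), so the generator truth
  equals the regression estimand; r = 0.45 puts the 12-item α near the
  published 0.87 after ordinal attenuation.

What the generator does **not** emulate: real text (documents carry only
probabilities), nonresponse and raking structure, geography, secular
news-cycle seasonality, cross-valence correlation of coverage, or
editorial syndication (duplicate stories).  Passing tests therefore
demonstrate that the pipeline's statistics are correct and well
calibrated under the assumed data-generating structure — not that the
substantive effect exists in any real corpus.

## Problem sizes and numerical choices

Statistical acceptance checks run at deliberately chosen sizes: odds-ratio
recovery at n ≈ 50,000 (45/day over the full period), type-I calibration
on 1,000 replications of a 200-day/2,000-respondent null study, the
bootstrap comparison on 200 date clusters with 1,000 cluster resamples,
and the screening/θ check across 100 full-length media simulations.
Coefficient recovery is judged against two Monte-Carlo standard errors
(the cluster-robust SE of the fit), a ≈ 95% criterion per term by
construction.  Eigen-decomposition uses `numpy.linalg.eigh` on the
correlation matrix; standardization uses the ddof = 1 sample SD
throughout; undefined precision/recall returns NaN with a warning rather
than a silent zero; pipeline artifacts are written with sorted JSON keys
and fixed float formatting so identical config + seed reproduce
byte-identical bundles, with the seed and config hash recorded in the
bundle's `manifest.json` (a sidecar, keeping the CSV/JSONL files strictly
standard).

## Known limitations

- The "mixed" valence label maps to both binary codes positive; the
  convention is defensible (such texts contain both valences, and the two
  binary classifiers are independent) but other mappings are coherent,
  and the choice matters only for corpora rich in mixed texts.
- Survey weights are importance weights; no design-based (linearization)
  variance is offered beyond the date-clustered sandwich, and the
  multilevel sensitivity model applies the same weights in the weighted
  marginal likelihood.
- The 28-day pro-valence θ runs higher in simulation than its published
  counterpart: longer windows average away idiosyncratic noise faster
  than the (unpublished) day-level noise structure of the real sources
  apparently did.  Only the 7-day reliabilities are calibration targets.
- σ̂ in the random-intercept model is a boundary MLE; in truly
  independent data it is 0 with sampling noise of order 0.1–0.2 at a few
  hundred modest clusters.
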