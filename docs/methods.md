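# Methods

`moodcast` implements a two-phase machine-learning pipeline for forecasting
next-hour depressed mood from passively sensed smartphone data, together
with a synthetic cohort generator that emulates the kind of ecological
momentary assessment (EMA) study the pipeline is designed for: ~31 persons
enrolled ~8 days, hourly on-the-hour sensor indexing, and wake-hour mood
prompts answered with imperfect compliance.

## The predictive model

For every target hour *t*, a window collects all person-hours in the
half-open interval [*t*−24, *t*) that have an observed mood composite.
Training only ever looks backward; rows at or after *t* can never enter a
training set, which the test suite enforces bit-exactly (corrupting every
future outcome leaves hour-*t* predictions unchanged).

**Phase 1 (nomothetic).** One pooled gradient-boosted tree ensemble
(XGBoost; default 100 rounds, depth 3, learning rate 0.1 — the original
study does not state its settings) regresses the *within-person-centered*
mood composite on the hour's sensor features.  Centering uses each person's
training-window mean (cohort mean for persons absent from the window), so
the pooled stage models intraindividual variability.  Its predictions are
not of interest themselves; they are appended to the design matrix as one
stacked feature (p → p+1).

**Phase 2 (idiographic weighting).** Per person and per target hour, a
randomized-forest regression is fitted on the stacked window with
observation weights: the target person's rows weigh 1.0, everyone else's
0.2.  The forest's per-split candidate count is tuned over three evenly
spaced integers in [1, p] crossed with the split rule (variance-based CART
vs extremely randomized trees), scored by person-blocked 3-fold
cross-validation *inside the training window*.  Ties go to the smaller
candidate count, then to the variance rule (more regularized first).  Two
degeneracies hold exactly by construction and are tested: equal weights
reproduce the unweighted pooled forest, and zero other-weight reproduces a
forest fitted on the person's rows alone.

Bulk simulation runs (test suite, acceptance script) disable the grid
search and use `max_features = sqrt(p)` with the variance rule and forests
of 100 trees; grid-search behaviour is exercised on dedicated small
fixtures.  This is a footprint choice, not a statistical one — the
degeneracy, leakage, and counting contracts are independent of it.

**Seeds.** Every fit draws its seed from the master seed keyed by
(imputation copy, target hour, person slot), never by execution order, so
any single fit is reproducible in isolation and results are independent of
parallelism.

## Outcome and features

The momentary outcome is the arithmetic mean of the available "sad" and
"lonely" ratings (0–100).  How the original study combined the two items is
unstated; equal weighting of two comparably loading depressed-affect items
is the package default and is switchable.  Sensor features are used as
listed — raw latitude/longitude, location accuracy/speed/source/type,
temperature, humidity, precipitation, light, mean HR, RMSSD, hourly
outgoing-call counts — with the two categorical fields one-hot encoded
against a category dictionary frozen at pipeline start, keeping p constant
across windows.

## Multiple imputation

Sensor fields are completed *m* times (default 5; runs in this repository
use m = 2 as a footprint choice) by chained-equation-style conditional
draws: Bayesian-ridge regressions of each field on the other sensors,
person indicators and hour-of-day harmonics, with missing cells replaced by
posterior-predictive draws, clamped to the person's observed range when the
person has ≥ 3 observations of that variable (cohort range otherwise).
Categorical fields are drawn from the person's observed category
distribution.  Mood is never imputed and never used as an imputation
predictor — a deliberate firewall that makes the leakage guarantee hold
through the imputation stage.  Stochastic conditional draws carry
irreducible posterior-predictive noise, so they beat the variable's
marginal SD in mask-and-recover tests only where the sensors give real
conditional signal (conditional R² > 0.5); the test fixture provides it.

## Evaluation

Predictions are averaged over the m imputation copies per (person, hour).
Agreement is Pearson's r between observed and predicted mood: pooled over
all pairs (capturing inter- and intraindividual variability) and per person
(intraindividual only).  A single r gets a Fisher-z interval,
z ± 1.96/√(n−3).  Per-person correlations are averaged on the z scale
(atanh → mean → tanh) because r does not combine linearly; the interval for
the average is a t interval on the z scale with df = persons − 1.  Persons
with undefined correlations (constant observed mood, < 3 pairs) are
excluded from the average and reported.  Whether the original study used
Fisher-z, bootstrap or model-based intervals is unstated; Fisher-z is the
conventional default.

## Sensitivity analyses

Both are linear mixed models with a person random intercept, estimated by
REML with a fitter implemented in this package (no installed Python library
exposes Satterthwaite degrees of freedom; coefficients are cross-checked
against statsmodels MixedLM in the tests, and constraining the random
intercept variance to zero reproduces OLS):

1. *Race moderation*: mood ~ prediction × race + (1 | person); a joint F
   test over all prediction × race interaction terms with
   Satterthwaite-type (fractional) denominator df pooled across contrasts
   in the lmerTest manner.  The race reference level is the most frequent
   category; the F statistic is invariant to relabeling.
2. *Lagged-outcome control*: mood_t ~ prediction_t + mood_{t−1} +
   (1 | person), with the lag defined strictly as hour t−1 (rows without a
   previous-hour outcome are dropped; imputation-averaged values are used
   where the previous hour was only partially observed).  Predictions that
   literally equal the lag are flagged as collinear rather than
   interpreted.

Under null generators both are calibrated: moderation p-values are uniform
(KS test over 200 replicates) and the prediction slope's CI covers zero for
white-noise predictions at the nominal rate.

## The synthetic cohort

No raw data from the motivating study are deposited, so the generator is a
first-class, tested component.  Its defaults are the study conditions:
31 persons, 8 enrollment days, 16 wake hours/day, prompts on the first 7
days answered with probability 0.46 (≈ 52 completed prompts per person),
hourly sensors with 5% MCAR dropout.

* **Latent mood** per person-hour = habitual level + AR(1) chain
  (φ = 0.7, innovation SD 6) + 24-h sinusoid (amplitude 8 mood units).
  The habitual level is anchored to the baseline DASS depression score
  (14 items rated 0–3; attainable total exactly [0, 42]):
  27 + 0.6·(DASS−20) + N(0, 4).  Published EMA studies of this design do
  not report a within-day generative mood model; AR + diurnal + intercept
  is the standard description of hour-to-hour mood fluctuation in that
  literature.
* **Readouts**: sad and lonely are the latent state plus independent item
  noise sized so their correlation is ≈ 0.66 at default settings, clipped
  to [0, 100]; an optional zero-inflation knob emulates floor effects and
  is off by default.
* **Couplings**: each coupled sensor shifts with the latent state
  standardized by a *fixed cohort reference scale* (z = (L−32)/12): per
  1 SD of worse mood, HR +4 bpm, RMSSD −6 ms, light −120 lux, speed
  −0.15 m/s, and outgoing calls ×e^(−0.5) (Poisson log-rate).  Directions
  are face-valid defaults, fully configurable, and per-person
  heterogeneity (SD 0.5 of the multiplier) plus an optional sign-flip
  fraction create the interindividual differences the idiographic stage
  exists for.  Normalizing by a cohort constant rather than within person
  keeps habitual severity visible in the sensors — without it no pipeline
  could recover interindividual variability from passive data.
* **Weather** (temperature, humidity, precipitation) is cohort-shared —
  one site — and location is a small set of per-person anchor points
  (home, university, gym, …) with GPS jitter standing in for a places API.
* **Heart metrics** are emitted directly; an inter-beat-interval → RMSSD /
  mean-HR utility lives in the panel module for real-data ingestion.

**What the generator does not emulate**: measurement drift, battery-driven
systematic missingness, location semantics beyond the anchor categories,
weekday/weekend structure, or informative (MNAR) prompt skipping.  Passing
tests show the pipeline recovers structure it is pointed at and invents
none where there is none; they cannot certify real-data effect sizes.

### Null-calibration cohorts

Two subtleties matter when testing that the pipeline does not hallucinate
signal.  First, sensor diurnal cycles are clock-driven, so with couplings
off the sensors still share a 24-h clock with the mood sinusoid; the
coupling-channel independence test switches the mood diurnal term off.
Second, with heterogeneous habitual levels, the idiographically-weighted
forest genuinely predicts each person's *level* from their training
outcomes (location fingerprints + observation weights), so the pooled r is
positive even with zero coupling — the same mechanism that makes pooled
agreement exceed within-person agreement in this design.  The null-
calibration runs therefore use the fully null cohort (couplings, diurnal,
AR and level heterogeneity all zero), in which mood has no predictable
structure at all.

## Problem sizes and numerical choices

Simulation-heavy tests run at reduced scale, chosen once: recovery and
benefit cohorts of 8–15 persons, strided target-hour grids (every 4th–8th
hour), m = 2 imputations, forests of 50–100 trees.  The recovery-
monotonicity check (pooled r non-decreasing in coupling scale over
{0, 0.5, 1, 2}) averages 5 seeds and uses a pre-set 0.02 Monte-Carlo
allowance.  Degenerate inputs are signalled, not NaN-propagated: undefined
correlations, insufficient pairs, skipped windows and untestable moderation
each raise a dedicated exception that callers log and report.  |r| = 1 is
clamped to 1−1e−7 (with a warning) before Fisher transformation.
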