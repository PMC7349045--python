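# moodcast

Hour-to-hour forecasting of depressed mood from passively sensed smartphone
data, for researchers studying short-timescale mood dynamics and
just-in-time adaptive interventions.

Depressed mood fluctuates substantially within a day, but most digital
phenotyping work predicts severity across weeks.  This package implements a
pipeline that predicts the *next hour's* momentary depressed mood (the mean
of 0–100 "sad" and "lonely" ratings) from the preceding 24 h of passive
sensing — location, weather, light, photoplethysmographic heart rate and
RMSSD heart-rate variability, and outgoing-call counts — and quantifies how
well those predictions generalize both across and within persons.  Because
studies of this design rarely deposit raw data, the package ships a
first-class synthetic cohort generator with known ground truth, so every
stage is testable end to end.

## The model

For each target hour *t* (rolling origin, never looking forward):

1. **Nomothetic stage** — one pooled XGBoost regression of the
   within-person-centered outcome on the sensor features, fitted on all
   person-hours in [*t*−24, *t*) with an observed outcome:

       mood*_{i,s} = f(x_{i,s}) + ε,   s ∈ [t−24, t),
       mood*_{i,s} = mood_{i,s} − mean_i

2. **Idiographic weighting** — per person *i*, a randomized-forest
   regression on the same window with the nomothetic prediction appended as
   a stacked feature (p → p+1) and observation weights w = 1 for person
   *i*'s rows, w = 0.2 for everyone else's; per-split candidates and split
   rule (variance vs extremely randomized) tuned by person-blocked CV
   inside the window.

3. **Evaluation** — out-of-sample hour-*t* predictions, averaged over m
   imputation copies, scored by Pearson r pooled over all pairs and per
   person; per-person r's are combined via Fisher's z
   (r̄ = tanh(mean atanh r_i)) with a t-based interval on the z scale.

4. **Sensitivity** — random-intercept mixed models (REML, Satterthwaite
   df): a joint F test of prediction × race interactions, and the
   prediction slope controlling for the lagged outcome,
   mood_t ~ β₀ + β₁·pred_t + β₂·mood_{t−1} + u_i.

Sensor panels are completed by chained-equation multiple imputation (the
outcome is never imputed and never used as an imputation predictor, so no
future outcome can leak into any feature).

## Worked example

The numbered scripts under `analysis/` run the full study-shaped analysis
on a synthetic cohort (31 persons × 8 days, ≈46% prompt compliance):

```
$ python analysis/01_simulate_cohort.py --seed 1
panel: 31 persons x 192 hours (5952 person-hour rows)
completed mood prompts per person: mean 51.58 (range 41-61); total 1599

$ python analysis/02_fit_models.py --seed 1
dry-run plan: 4464 idiographic fits per imputation (31 persons x 144 target hours)
performed 672 idiographic fits over 36 target hours (stride 4); 672 prediction records

$ python analysis/03_evaluate.py
pooled r = 0.736, 95% CI [0.683, 0.781], n = 336 person-hours
Fisher-z average per-person r = 0.693, 95% CI [0.609, 0.761]
strongest per-person correlation: p012 r = 0.951

$ python analysis/04_sensitivity.py
race moderation: F(1, 319.2) = 0.006, p = 0.937
lagged-outcome control: beta1 = 0.801, SE = 0.142, t(64) = 5.625, p = 4.4e-07
```

Reading these numbers: the pooled correlation mixes inter- and
intraindividual variability; the Fisher-z average isolates how well the
models track each person's own hour-to-hour fluctuation; a
non-significant moderation F says predictive performance does not differ by
race group in this cohort; and a positive β₁ under the lag control says the
models do more than carry the last observation forward.  The synthetic
cohort has stronger, cleaner sensor-mood couplings than real phones
deliver, so its correlations sit above those typically reported for real
EMA cohorts — the generator exists to make the machinery testable, not to
claim effect sizes.

The same pipeline is scriptable through a CLI
(`moodcast simulate | run | evaluate | all`), e.g.
`moodcast all --seed 7 --out results/demo`, which also writes a manifest
with content hashes and the realized fit counts.

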