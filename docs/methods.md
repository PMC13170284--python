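# Methods

This note records the models, conventions and numerical choices behind
`cogload`, and what the synthetic-data tests do and do not establish.

## Sessionization and metric derivation

Raw audit-log rows are (provider, CSN, event type, timestamp). For one
provider's chronologically ordered stream across all CSNs:

* each event's **active time** is min(gap to the provider's next event
  in *any* CSN, timeout), with timeout = 600 s. The cap is stated in the
  source method only for the encounter-final event; we apply it
  uniformly so a provider who walks away mid-encounter is treated the
  same as one who walks away at its end. An event with no successor
  contributes exactly the timeout.
* a **segment** closes when the next event belongs to a different CSN or
  the gap exceeds the timeout; segment end = last event time + its
  active time. Segments for one (provider, CSN) pair are disjoint by
  construction, and total active time equals the sum of segment lengths.
* **merging**: maximal runs of equal consecutive event types within a
  CSN's stream collapse to one event whose active time is the run's sum.
  Merging applies across segment boundaries too (an open screen that
  idles out and resumes is still one activity); it is idempotent.
* events with identical timestamps keep their input order (stable sort);
  with `assume_sorted=True`, rows that step backwards in time (clock
  skew) are dropped with a warning and a count.

Metrics per provider-encounter: loops = merged events − distinct types
(every revisit occurrence counts: A,B,C,A,B,D has two loops — this is
the only reading consistent with the worked example), distinct = unique
types, duration = total active seconds / 60, average event time = total
active seconds / merged event count. The average uses the *merged*
denominator; the merge exists precisely because raw duplicate rows would
otherwise inflate the event count, so the merged count is the meaningful
unit of activity.

For the ML stage, multi-provider encounters are pooled: every provider's
merged events, ordered by time, form one encounter-level stream; merged
entries from different providers are not re-merged.

## Eligibility

The four statin indications are pooled into one eligible category. The
printed inclusion table couples LDL ≥ 190 mg/dL with a T2DM diagnosis;
we follow it as printed and expose `ldl190_requires_diabetes=False` for
the conventional reading (LDL ≥ 190 alone). T2DM is diagnosis-code flag
OR HbA1c ≥ 6.5%. Exclusions dominate all inclusions and are checked
first. Any PCE input missing or older than the 3-year lookback (applied
uniformly to all dated inputs; "most recent" = latest dated value, ties
broken by record order) makes the patient ineligible with reason
`missing_risk_inputs`.

The 2013 Pooled Cohort Equations coefficients (four sex/race strata,
group mean linear predictor, 10-year baseline survival) are embedded as
versioned JSON package data, overridable per call; an externally
computed risk column can be injected via `risk_override`. Race
categories outside the published strata map to the non-Black coefficient
set. The implementation reproduces the guideline's printed reference
profile (55-year-old, TC 213, HDL 50, untreated SBP 120, nonsmoker,
nondiabetic) to the printed precision: 2.1/3.0/5.3/6.1% across strata.
The code-set lists shipped in `data/code_sets_synthetic.json` are
synthetic stand-ins (the study's supplementary lists are not public) and
exist so the classification logic is configurable and testable.

## Regression

Initiation per provider-encounter is fitted by ML logistic regression:
four metrics (quadratics on loops and distinct events by default, on the
raw scale so −β₁/(2β₂) reads in metric units; centering is a config
switch), covariates (age, active-diagnosis count, Elixhauser index, sex,
race/ethnicity, insurance class with male/White/commercial references),
and provider fixed effects as explicit indicator columns. Providers
whose outcome never varies are perfectly predicted by their own
indicator and are dropped with a logged count (standard
incidental-parameter handling). Covariance is the cluster sandwich on
the encounter id as implemented by statsmodels (small-sample correction
included). AUROC is in-sample. The linear-vs-quadratic comparison is a
joint Wald test of the quadratic coefficients under the clustered
covariance; average marginal effects use a central finite difference
with step max(1e-4, 1e-4·range). Trimming sensitivity drops, per metric
separately, rows strictly outside the [1%, 99%] type-7 quantile band and
refits.

## Boosted attribution

`xgboost` and `shap` are not available in the supported environment, so
the boosted model is scikit-learn's `GradientBoostingClassifier`
(logistic deviance, learning rate 0.1, depth 6, no subsampling — the
unstated hyperparameters are fixed in the trainer's signature) grown one
tree at a time under warm starts, with validation-AUROC early stopping
(patience 10, cap 300) per repeat of a 70/15/15 split; splits missing a
class are redrawn and logged. SHAP values come from a from-scratch exact
path-dependent TreeSHAP (`cogload._treeshap`, numba-jitted with a pure
Python fallback), unit-tested against brute-force Shapley enumeration
over feature subsets and against the additivity identity
Σφ + base = margin (holds to ~1e-15 here; the documented contract is
1e-4).

Aggregation across repeats follows the source convention: per-feature
mean SHAP (direction) and mean |SHAP| (magnitude) per run on that run's
test rows; the 95% CI of the mean is a t-interval across run-level means
by default (`ci_across="observations"` pools rows instead — the source
does not say which axis the CI uses); features with a CI containing
zero, or identically zero SHAP, are filtered; relative contribution
normalises global means over the significant set.

A structural caveat the tests document: for a model driven by a single
isolated feature, its dataset-mean SHAP equals the evaluation-vs-training
mean-margin gap, which is zero in expectation; the signed mean SHAP is
therefore informative only through multi-feature credit redistribution,
and a clean one-feature planted-signal experiment recovers the feature's
*rank* (by global mean |SHAP|) but cannot stably certify significance or
direction of its signed mean.

Pre-decision truncation cuts each encounter at the first statin order
(initiated; a missing order time is a data-integrity error), else at the
first configured order-screen event, else at encounter start + the
median time-to-order among initiated encounters. Events strictly after
the cut are removed, and the boundary event's dwell is censored at the
cut so no active time beyond it is counted. Loop counts, shown flags and
per-type *total* active time are then monotone under truncation; the
per-type *average* (total/occurrences) — the reported feature — is not
mathematically monotone (dropping short late occurrences can raise it),
which the tests reflect by asserting monotonicity for the three monotone
quantities.

## Synthetic-data generator

The generator emulates the study's data structure, with defaults fixed
once from the reported marginals:

* provider-type shares 0.8241/0.1166/0.0593 (physician/NP/PA);
  encounters involve 1/2/3 providers with shares 0.732/0.237/0.030
  (printed shares summing to 0.999 are renormalised exactly).
* merged events per provider-encounter: rounded log-normal, median 100,
  σ = 0.35; each non-initial event opens a new type with per-encounter
  probability p ~ Beta(mean 0.31, concentration 60) while unseen types
  remain, otherwise revisits a seen type other than the current one
  (first-order revisit mechanism). This yields loops ≈ 72 and distinct
  ≈ 34 on average, near the reported 73/34.
* within-segment dwells: log-normal (median 5 s, σ = 1), scaled by a
  per-provider-encounter log-normal pace multiplier (σ = 0.6) — the
  reported average-dwell dispersion (SD above the mean) requires a
  shared within-encounter pace factor — truncated below the timeout and
  quantized to milliseconds so ground-truth bookkeeping is exact in
  double precision. Sessions have 2 segments (chart review + visit)
  plus an after-hours segment with probability 0.3; inter-segment idle
  is timeout + log-normal (median 30 min). With these laws mean duration
  ≈ 38 min and mean dwell ≈ 24 s/event.
* a merged event is logged as two consecutive raw rows with probability
  0.25, exercising the merge rule without changing ground truth.
* outcomes: Bernoulli through the quadratic logistic model at the
  published fitted coefficients; the unreported intercept defaults to
  −0.5, chosen so the implied initiation rate at mean covariates is
  ≈ 46%, near the observed 45.5%, and provider intercepts are N(0,
  0.25²) (their distribution is unreported). Each provider-encounter row
  draws an independent outcome given its own metrics, which keeps the
  generative model exactly the fitted model for recovery testing;
  initiated rows place the order time uniformly within active time,
  mapped into a real segment.
* ages are truncated-normal(60.8, 11) on [20, 75] (mean ≈ 58.7, median
  ≈ 61); other covariate and lab marginals are plausible round numbers
  for a statin-eligibility cohort and are documented in
  `simulate_patients`.

`simulate_metrics` draws metric rows from the same laws without
materialising event streams; the Monte-Carlo regression studies use it
for speed, while the event-level generator backs the self-consistency
tests (metric engine output equals generation-time bookkeeping exactly
for counts and to ~1e-15 relative for times).

What a green test establishes: the pipeline recovers its own generating
process — sessionization inverts the generator, the regression recovers
the generating coefficients with nominal CI coverage, the Wald test is
calibrated under the null, and attribution surfaces a planted signal.
What it does not establish: agreement with the study's real-data
descriptives, coefficients, AUROCs or SHAP magnitudes, which depend on
data that are not deposited; real logs also carry behaviours the
generator omits (vendor-specific event semantics, within-day scheduling
structure, informative missingness, correlated patient mix across
providers).

## Known limitations

* Provider fixed effects by dummy absorption are subject to
  incidental-parameter bias when encounters per provider are few; the
  recovery tests use ≥100 encounters per provider where this bias is
  negligible for the metric terms.
* The average-dwell and duration coefficients are weakly identified in
  any data with this metric structure (average = 60·duration/merged
  count), so their estimates are unbiased but noisy at moderate n.
* `classify_outcome` matches statin orders by case-insensitive name
  against a configurable list; no RxNorm normalisation.
* The boosted model is gradient boosting with exact splits; at the full
  215-type vocabulary and tens of thousands of encounters, training 200
  repeats is compute-intensive — the reduced desk-scale defaults (fewer
  repeats, smaller vocabularies) are used in tests and examples, with
  the full settings available through the function arguments.
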