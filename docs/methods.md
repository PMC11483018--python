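# Methods

This note documents the models and procedures implemented in `ppdwear`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generator does and does not emulate.

## Cohort phenotyping

A woman is assigned to the PPD cohort when her EHR contains at least one
qualifying event — PPD diagnosis, depression diagnosis, or antidepressant
exposure — strictly after delivery and within the postpartum window
(`ppd_window_months`, default 24 months, implemented as exactly 730 days
so window lengths are leap-year-independent). When several events
qualify, the **earliest** becomes the index date: earliest onset is the
conservative clinical reading, and it makes the index invariant to the
order in which events arrive. Event classes are taken at face value; no
attempt is made to infer the indication behind an antidepressant
prescription, and concept-set curation (which diagnosis/drug codes map to
each class) is upstream of this package.

Women without a qualifying event form the non-PPD cohort. Their
PPD-equivalent index sits `ppd_equivalent_offset_days` (58) after
delivery — the PPD cohort's median diagnosis delay — so that both cohorts
have an aligned fourth analysis window.

## Timeline segmentation

Four closed day-intervals per woman:

| period | interval |
|---|---|
| pre-pregnancy | `[index − 730 d, pregnancy_start − 1 d]` |
| pregnancy | `[pregnancy_start, min(delivery, ppd_start − 1 d)]` |
| postpartum | `[delivery + 1 d, index − 15 d]` |
| PPD window | PPD: `[index − 14 d, index + 30 d]` (45 d); non-PPD: `[index, index + 30 d]` (31 d) |

Design choices worth stating:

* **Pre-pregnancy is anchored at the index date**, not at pregnancy
  start, so its length depends on diagnosis timing. That is deliberate:
  the analysis asks about behaviour in the two years leading up to the
  index event.
* **The PPD window takes precedence.** It reaches 14 days back before
  the index (depressive symptoms must persist ~2 weeks before a diagnosis,
  and same-day antideprescriptions take ~4 weeks to act), so postpartum is
  truncated at `index − 15 d`; with an index within a fortnight of
  delivery the window can even cross the delivery date, in which case
  pregnancy is truncated the same way. This keeps the four periods
  pairwise disjoint for every input, which the test suite asserts by
  enumeration.
* For non-PPD women the span `[index − 14 d, index − 1 d]` belongs to
  **no** period — these women never experienced onset, so those days are
  dropped from every denominator rather than being relabelled.
* Degenerate windows (start after end, e.g. postpartum under a very early
  diagnosis) are returned flagged-empty, never silently dropped.

Eligibility: a woman is analysed only if at least one day of device data
falls inside one of her periods on/after her first device day.

## Wear-time biomarkers

Hours worn per day are inferred from step presence: an hour with at least
`wear_hour_min_steps` (1) steps is a wear hour; a day with at least
`worn_day_min_hours` (1) wear hours is worn. Sleep wear is an independent
per-date binary (any main-sleep record). The literature's "valid day"
(≥ 10 wear hours, 100–45 000 steps) is computed as a diagnostic flag but
never filters anything: sparse wear is the phenomenon under study, not
noise to remove.

Period summaries use **calendar-day denominators**: every day of the
period counts, recorded or not, with absent days counting as not worn.
The only clipping is the ownership filter — the denominator starts at
`max(period start, first device day)`. Percentages are on the 0–100
scale. Consistency is the longest run of consecutive worn days in the
window; a worn-every-other-day pattern over 50 days scores 50 % worn but
a run of 1, which is exactly the distinction the statistic exists for.

## Inference

**Percent metrics (per-person, per-period).** One OLS per period:
`pct ~ cohort + age + race/ethnicity`, treatment coding with the non-PPD
cohort and the modal race level as references. Group effects are
estimated marginal means: predictions on a reference grid holding age at
its sample mean and weighting race levels **equally** by default
(`emm_weights: proportional` switches to observed frequencies; the EMMs
are invariant to the reference-level choice, which tests assert). The
cohort contrast uses a t statistic on the OLS residual df. Women with an
empty-flagged summary in a period are excluded from that period's model
rather than imputed — each model is a per-period cross-section.

**Daily hours (day-level, worn days only).** Because each woman
contributes many days, hours are modelled with a person-level random
intercept: y_ij = x_ij'β + b_i + e_ij, b_i ~ N(0, σ²_b),
e_ij ~ N(0, σ²_w), fitted by REML. Implementation: the likelihood is
profiled over λ = σ²_b/σ²_w. At fixed λ each person-block of the marginal
covariance is I + λJ, whose inverse is I − λ/(1 + λn_i)·J
(Sherman–Morrison), so the GLS estimate, profiled σ̂²_w, and the REML
criterion reduce to per-person sums; λ is then optimized by a bounded
scalar search on log(1 + λ) ∈ [0, 30] to relative tolerance 1e-8, with
the λ = 0 boundary checked explicitly. Fixed-effect covariance is
σ̂²_w·(X'V*⁻¹X)⁻¹. Inference uses residual df = n_obs − p; Satterthwaite
or Kenward–Roger corrections are out of scope, a documented divergence
from lme4/lmerTest defaults that matters only at very small group counts.
The fitter is cross-checked in tests against the balanced-design ANOVA
closed form, against statsmodels MixedLM on unbalanced data, and against
OLS when σ²_b = 0.

**Correlations.** Pearson r between the same per-person metric in two
periods (pre-pregnancy↔PPD, pregnancy↔PPD), within cohort; pairs with an
empty-flagged member are dropped; p from t = r·√((n−2)/(1−r²)) on n−2 df.
Zero-variance inputs and n < 3 raise rather than returning NaN.

No multiple-testing correction is applied across periods or metrics; the
four per-period models are reported as-is.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not the
full richness of consumer-wearable data:

* **Anchors.** Delivery uniform over a two-year span; pregnancy start =
  delivery − 280 d; PPD onset = delivery + round(LogNormal(median 58 d,
  σ = 0.7)), resampled above the 730-day cap so every intended PPD woman
  qualifies; a configurable fraction of non-PPD women receive a
  depression diagnosis at delivery + 800 d to exercise the window edge.
  The log-normal **shape** is a modelling choice (only the median is
  calibrated); σ = 0.7 puts quartiles near 36–93 days, a plausible
  diagnosis-delay spread.
* **Wear process.** Each day is worn with probability
  p' = logit⁻¹(logit(p) + b_person), where p is the cohort × period
  probability and b_person ~ N(0, `propensity_sd` = 0.6) is shared across
  periods — the mechanism that produces positive cross-period wear
  correlation. Day-to-day dependence is a two-state Markov chain that
  copies the previous day's state with probability `wear_persistence`
  (0.3 default; 0 gives i.i.d. days with marginal exactly p). Note the
  logit-scale propensity makes the population mean worn fraction sit
  slightly below p for p > ½ (Jensen); parameter-recovery runs therefore
  set `propensity_sd = 0`.
* **Hours and steps.** Worn days get round(TruncNormal(μ_person, σ_w = 2,
  [1, 24])) wear hours, μ_person = cohort × period mean + N(0,
  σ_b = 1.5), spread over distinct clock hours with ≥ 1 step each — so the
  daily-wear derivation inverts the generator exactly. Step magnitudes
  are arbitrary positives; circadian shape, heart rate and
  activity-intensity realism are non-goals.
* **Sleep.** Bernoulli per day, conditional on worn state
  (`sleep_given_worn` per cohort × period, `sleep_given_not_worn` = 0),
  calibrated so the *unconditional* sleep-wear probability equals the
  published adjusted sleep-wear means.
* **Calibration.** Defaults are the published cohort: 41/101 women,
  worn-day probabilities 0.729/0.589 (postpartum) and 0.707/0.556 (PPD
  window), hours means 14.4–17.8 by cohort × period, sleep probabilities
  0.589/0.456 and 0.644/0.498, ages ~ N(33, 4), two race levels at 87.8 %
  / 75.2 % majority. Pre-pregnancy and pregnancy wear/sleep levels were
  published only as "no significant difference", so both cohorts share
  mid-range values there (wear 0.57/0.63, sleep 0.45/0.50) — chosen once
  as plausible adherence between the reported levels and not revisited.
  Person-level dispersion (`propensity_sd`, hours σ_b) is set for stable
  parameter recovery, not to match the restricted source data, whose
  person-level variance is not published.

Passing tests on these cohorts demonstrates that the pipeline's
*machinery* is correct (phenotyping round-trips, denominators, estimators
recover known truth); it cannot demonstrate that the published effect
exists in any real population, since the generator injects the effect by
construction.

## Numerical and reporting choices

* Dates are whole calendar days, intervals closed, no time zones.
* Rank-deficient designs raise with the collinear columns named; factor
  levels absent from the data simply do not appear in the design.
* Percentages in the descriptive report are rounded to one decimal;
  age median/IQR use linear interpolation (type-7 quantiles).
* Race/ethnicity cells with fewer than `suppression_threshold` (20)
  persons are masked in the report, mirroring the dissemination policy of
  the motivating research program.
* Full determinism: one `numpy` Generator per simulation seed; identical
  seeds produce byte-identical CSVs and reports.
* Problem sizes in the recovery runs (400 women per cohort for percent
  metrics, 200 × 30 days for the mixed model, 5 000 pairs for
  correlations, 2 001 onset draws) were chosen so Monte-Carlo error is a
  small fraction of the quantities being recovered while runs complete in
  seconds.

## Known limitations

* Hours-from-steps is a proxy for true on-wrist time; an hour of wear
  with zero steps is invisible, so hours (and the 1-hour worn-day rule)
  undercount sedentary wear.
* Sleep episodes crossing midnight are attributed to whatever date the
  data producer assigned; the package takes the per-date flag as given.
* One delivery per woman; multiple pregnancies in the lookback window are
  out of scope.
* The LMM fits a single random intercept — no random slopes, no serial
  correlation within person beyond the intercept.
* Residual-df inference for the LMM is anti-conservative for very few
  persons; with the cohort sizes this package targets (tens to hundreds)
  the difference is negligible.
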