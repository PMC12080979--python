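# Methods

This note documents the models, conventions and design choices behind
`dkaudit`: what each stage assumes, which knobs matter, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## Case definition and detection

DKA is defined by the UK inpatient (JBDS-IP) composite criterion —
hyperglycaemia (glucose > 11 mmol/L) *or* documented diabetes, together
with ketosis (blood ketones > 3 mmol/L, or a urine dipstick of ++ or more)
and acidosis (pH < 7.30 or bicarbonate < 15 mmol/L). Resolution requires
pH > 7.30 or bicarbonate > 18 mmol/L with blood ketones < 0.6 mmol/L
sustained for two consecutive hours. All thresholds live in one
`Thresholds` record and are configurable; the defaults are the guideline
values.

Detection choices, where the guideline wording leaves room:

* **Point-in-time evaluation.** The criterion is evaluated at each
  observation timestamp using the most recent reading of each analyte. A
  **lookback of 6 hours** (configurable) bounds staleness: ward labs are
  drawn at least 1–2-hourly during DKA treatment, so a 6 h-old value is no
  longer clinically current, and an unbounded lookback would let a day-old
  glucose validate a diagnosis. Within the lookback, a missing pH is
  covered by bicarbonate (and vice versa); if *no* ketone datum or *no*
  acid-base datum exists the evaluation is **indeterminate** (`None`),
  which the detectors treat as not-met but which callers can distinguish
  from a definite `False`.
* **"Two consecutive hours"** is operationalised as two readings
  60 ± 15 minutes apart at both of which the resolution condition holds —
  real monitoring is not exactly hourly and the guideline states no
  tolerance. The tolerance is configurable, as is whether the resolution
  is stamped at the first or (default) the second reading of the pair; the
  default reflects that sustainment is only *established* at the second
  reading. A continuously-satisfied-2-h-interval reading of the phrase
  would be an alternative; the two-readings interpretation matches how
  ward charts are actually reviewed.
* **Urine ketones** may substitute for blood ketones in the diagnosis arm
  only; resolution is defined on blood ketones alone.
* **Manual adjudication.** Real audits confirm screened cases by hand. The
  deterministic stand-in is the diagnosis detector itself; an optional
  `confirmed` column reproduces a human override (`false` vetoes an
  episode, `true`/absent defers to the detector).
* **Ties** at the same minute are resolved in file order, for determinism.

## Adherence scoring

* **FRIII**: `(rate / (weight/10)) × 100`, scored on the *first* insulin
  infusion prescription by start time. The 2021 two-rate revision
  (0.05 units/kg/h once glucose falls below 14 mmol/L) is deliberately not
  folded into the score: the audited formula has a single rate, and
  scoring later rate reductions against it would mislabel guideline-
  compliant de-escalation as under-dosing. This is a known simplification.
* **Fluids**: the replacement schedule is a bolus plus 1 L bags over
  1, 2, 2, 4, 4 and 6 hours, then 6-hourly until resolution. The bolus is
  counted as **1000 mL** (two 500 mL boluses): with whole-bag accrual this
  is the unique natural calibration that makes the schedule recommend an
  integer 4 L for a 5 h episode, the anchor the guideline arithmetic uses.
  **Whole-bag accrual** (a bag is credited once its interval completes) is
  the default because pro-rata accrual cannot hit that anchor; pro-rata is
  available as a config switch, and the whole schedule (bolus, bag list,
  continuation) can be replaced from YAML.
* **Monitoring**: readings per hour of DKA × 100, counted per analyte over
  the *closed* interval [diagnosis, resolution] — the closed interval is
  what makes a 5 h episode with hourly readings come out at exactly five
  readings = 100 %. Duplicate same-minute charting counts once per
  analyte. Over-monitoring (> 100 %) is not truncated; it simply falls out
  of band beyond 120 %.
* **Banding**: 80 ≤ pct ≤ 120, both bounds inclusive (the conventional
  reading of "80–120 %"), always evaluated at full precision; the 1-d.p.
  rounding in CSV outputs is presentation only.

## Complications, outcomes, summaries

Complications are flagged at **episode level** (≥ 1 qualifying reading
flags the episode once), over the DKA window — diagnosis to resolution, or
to discharge for unresolved episodes — so proportions cannot exceed 1 and
denominators are episode counts. Hypokalaemia and hyperkalaemia may
coexist on one episode (excursions at different times). Potassium values
partition as < 3.5 / 3.5–5.5 inclusive / > 5.5 mmol/L.

Unresolved episodes contribute to complication denominators and length of
stay, but not to duration medians (no imputation).

Medians and IQRs use the **Hyndman–Fan type 6** quantile convention
(linear interpolation at position (n+1)p; numpy method `"weibull"`), the
default of SPSS-style audit outputs — under it, durations {4, 6, 8, 10,
12} give median 8 with IQR (5, 11). The convention is a module-level
constant (`QUANTILE_METHOD`) because the choice is visible at small
quarterly sample sizes.

## Quarterly aggregation and comparison

Episodes are assigned to calendar quarters (Q1 = Jan–Mar) by **admission
date** — the admission defines the care episode. Per indicator, episodes
whose score is absent (unresolved DKA, no FRIII prescription) leave that
indicator's denominator only. Pooled rows (`ALL`) are computed from the
per-episode records, so pooled counts are exactly the sums of hospital
counts and the pooled proportion is the episode-weighted mean of hospital
proportions.

First-vs-last change is an **uncorrected Pearson chi-square** (1 df) on
the 2×2 in-band × quarter table; Yates' correction is a config switch, off
by default. A hospital's first quarter is its earliest quarter containing
data, which reproduces staggered onboarding without hard-coding join
dates. Results with any expected cell below 1 are returned but flagged
unreliable; a table with a zero marginal carries no association
information and is reported as statistic 0, p 1, unreliable. Raw p-values
are reported; an adjustment across hospitals × indicators is deliberately
not applied by default, matching usual audit practice of flagging signals
for local review rather than formal inference.

Feedback reports are plain markdown rendered with deterministic f-string
formatting — byte-identical across runs on identical inputs — showing each
hospital its trailing four quarters next to the pooled series, with no
other hospital named.

## Synthetic cohort generator

The generator emulates the registry the pipeline is built for: 11
hospitals (A–K) onboarding in three waves over three years, per-quarter
Poisson episode counts whose means reproduce per-hospital totals of a
~2000-episode audit, lognormal weight (median 75 kg, IQR 63–89), age
(median 45 y, IQR 29–61), DKA duration (median 15 h, IQR 8–25 — bracketing
the 5–52 h range of quarterly hospital medians such audits report), and
length of stay (median 3.2 d, IQR 1.8–6.0); a male:female ratio of 1.29;
default in-band probabilities of 0.80 (FRIII), 0.40 (fluids), 0.40
(glucose) and 0.55 (ketones) and complication rates of 0.10/0.30/0.15
(hypoglycaemia/hypo-/hyperkalaemia), mid-scale values for an audit in
which fluid prescription and monitoring are the weak indicators; and 5 %
of discharge codes deliberately miscoded so the FRIII screening path is
exercised. Lognormals are parameterised by (median, IQR) via quantile
matching.

Construction is *truth-first*: adherence factors, complication flags and
durations are sampled, then records are built so the pipeline must recover
them —

* hourly lab panels with ± 5 min jitter (configurable up to 14 min), the
  final two panels exactly 60 min apart so the consecutive-readings rule
  fires at the intended hour;
* ketone/pH/bicarbonate trajectories that satisfy the resolution condition
  only at those final two panels;
* FRIII rate = weight/10 × factor and fluid volume = recommended(duration)
  × factor, so recovered percentages equal sampled factors exactly;
* monitoring counts chosen so the realised score falls on the intended
  side of the band (draws infeasible for an episode's length are flipped
  to the opposite out-of-band side, or the realised label recorded — the
  truth table is always exact).

In-band labels, complication flags and miscoding default to **quota
sampling**: exactly round(p·n) episodes per label, drawn by a seeded
permutation. This realises configured proportions exactly in every cohort,
so recovery checks test the pipeline's measurement fidelity rather than
Monte-Carlo noise; per-episode Bernoulli sampling remains available
(`band_sampling="bernoulli"`) when sampling variability itself is wanted.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: physiological kinetics (trajectories are
piecewise threshold-crossing constructions, not a metabolic model), missing
or erroneous charting, transcription noise in weights and volumes,
unresolved or fatal episodes, transfers, re-admissions, or any secular
trend in adherence (the generator is stationary, so first-vs-last
chi-squares on synthetic cohorts are null by construction). The pipeline's
behaviour on such messiness is covered only by the validation layer and the
randomised detector-vs-oracle tests.

## Problem sizes and numerics

The test suite runs on compact cohorts (25–500 episodes) plus randomised
sweeps of 300–1000 episodes against brute-force oracles; the analysis
drivers use the full ~2000-episode default cohort. All timestamps are
minute-resolution naive local times (single-country registry). Numeric
cells are written to CSV with `repr`, so cohorts round-trip bit-exactly.
Percentages are compared at full precision internally; acceptance-level
identities (e.g. fluid adherence of the recommended volume ≡ 100 %) hold
to 1e-9, the tolerance used where a product/quotient of doubles is
involved.

## Known limitations

* The fluid schedule's bolus calibration (1000 mL total) reproduces the
  4 L-at-5 h anchor but is a reconstruction of prose, not a published
  formula table; alternative tables drop in via config.
* FRIII scoring ignores the 2021 two-rate revision (above).
* Whether "two consecutive hours" means two hourly readings or a
  continuously satisfied interval is an interpretation; the former is
  implemented.
* Chi-square on small quarterly denominators is fragile; the unreliable
  flag surfaces this but no exact test is substituted.
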