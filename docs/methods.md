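# Methods

## The index

The ANU-ADRI is an additive point score. Each risk or protective factor is a
small categorical variable; every category carries an integer number of
points, and the individual's score is the sum over factors of the selected
category's points. Points originate from evidence synthesis: the pooled odds
or risk ratio of each factor category was log-transformed (the beta-weight)
and multiplied by a constant to give integers; `derive_points` implements
that transformation (rounding half away from zero, so protective ratios give
negative points), but the **bundled published point table**
(`src/anuadri/data/anu_adri.json`) — not `derive_points` — is the source of
truth for the shipped points. Age points are sex-stratified; age bands are
closed integer bands exactly as published (`<65`, `65–69`, …, `≥90`), and a
fractional age floors to its integer year before band lookup (age 64.6 is
"<65").

Scorecard variants are factor subsets mirroring what each validation cohort
measured: 10 factors for the memory-and-aging cohort (`anu_adri_map`, range
−13…64), 8 for the Swedish old-old cohort (`anu_adri_kp`; its smoking
variable retains only the never/current categories because only those were
asked), 9 for the cardiovascular-health cohort (`anu_adri_cvhs`, range
−11…56), and the 6-variable cross-cohort intersection (`anu_adri_common`:
age, sex, education, diabetes, smoking, alcohol — sex lives inside the
stratified age factor).

Two deliberate decisions in the point table:

* **Heavy alcohol** carries no published points. We default it to 0 (same as
  abstainers) and expose it as an override
  (`build_scorecard(..., overrides={"alcohol": {"heavy": k}})`).
* **KP range.** Summing the published per-factor extrema over the 8 KP
  factors gives (−3, 64); the source reports a maximum of 61 for that
  cohort, a discrepancy we cannot reconstruct from the published table. The
  package reports its computed (−3, 64). The MAP and CVHS ranges recompute
  exactly.

**Missing data.** The default `missing_policy="strict"` refuses to score a
record with any missing card factor, matching a complete-case analysis
(which is how the reported validation was run); `"skip"` scores the
remaining factors, counts the missing ones as 0, and lists them.

**CAIDE comparator.** The CAIDE midlife risk score (age, sex, education,
systolic blood pressure, BMI, cholesterol, physical activity) is carried in
the same representation (`caide`, plus `caide_no_bmi` and
`caide_no_bmi_no_chol`, since midlife adiposity/cholesterol weights are not
applicable to old-age cohorts). Its weights are not re-derived here; they
ship as configuration citing the original CAIDE publication and can be
overridden. Note a source ambiguity: the validation paper's summary lists
"sex (female)" among the CAIDE risk categories, while the original CAIDE
score assigns the point to men; we follow the original (male = 1 point).

## Synthetic cohorts

The validation cohorts are proprietary, so `anuadri.synthetic` generates
stand-ins. What it emulates:

* **Marginal factor frequencies** per cohort, taken from the published
  descriptive table (counts normalised within each factor; the sex marginal
  uses the printed percentage). Example targets for the
  cardiovascular-health preset: diabetes 16.0%, current smoking 10.9%.
* **Demography**: sex first, age band conditional on sex, then a uniform
  integer age within the band; the open-ended ≥90 band is bounded at 99, and
  each cohort's minimum entry age truncates its lowest band.
* **Factor availability**: fixture CSVs omit the columns a cohort never
  measured (e.g. no TBI column in the cardiovascular-health preset).
* **Follow-up**: exponential censoring with cohort means 3.5 / 6.0 / 6.0
  years.
* **Outcome**: a proportional-hazards time to dementia,
  `T ~ Weibull(shape, rate = h0 · exp(β · (score − mean score)))` with
  shape 1 (exponential) by default. Centring the score keeps
  `h0` interpretable as the hazard of an average-scoring participant.
  Defaults: `beta_per_point β = 0.05`, `baseline_hazard h0 = 0.02 /year`
  (with 6-year mean censoring this yields the ~11% incident-dementia
  fraction typical of the longer cohorts). An incident dementia is
  classified as AD with probability `ad_fraction = 0.75` (AD accounts for
  up to three quarters of dementia); for AD analyses a non-AD dementia acts
  as censoring at the event time, which is independent given the score, so
  Cox estimation of β remains consistent.
* **Missingness**: optional; a participant is incomplete with probability
  `missingness` and then has one uniformly chosen factor blanked. Per-factor
  missingness reconstructed from the published table's column sums would
  give a complete-case fraction of ~0.83 for the memory-and-aging preset,
  not the reported 903/1164 ≈ 0.776, so the participant-level model (which
  reproduces that fraction directly) is used instead.

What it does **not** emulate — and therefore what passing tests do not show
about real data: inter-factor correlation (factors are sampled
independently; only marginals are published), competing risk of death,
time-varying exposures, informative censoring, two-phase sampling designs,
and any real score–hazard coefficient (β defaults are chosen for test
power, not biological fidelity — the published c-statistics of 0.63–0.74
cannot be targeted without the real joint distribution). Everything is
deterministic given the config seed (NumPy `default_rng`).

## Evaluation pipeline

* **Filtering**: drop prevalent (baseline) dementia, records missing an
  outcome, and — under strict policy — records missing any card factor;
  exclusion counts are logged per reason and reconcile with the input n.
* **c-statistic**: Mann–Whitney form with midranks (ties count ½), computed
  on incident-case binary status rather than a time-dependent concordance,
  matching how the index's validation reports AUCs per outcome.
  Confidence intervals are DeLong by default (the original report does not
  name its CI method); a seeded stratified bootstrap (2000 resamples) is
  available for cross-checking. Degenerate-variance inputs (e.g. perfect
  separation) return a zero-width interval at the point estimate.
* **Quartiles**: cut points at the 25th/50th/75th sample percentiles
  (linear-interpolation quantile); intervals are (−∞,q25], (q25,q50],
  (q50,q75], (q75,∞) — boundary ties go to the lower quartile, matching the
  half-open printed quartile ranges ("13·1–21·0" style). With integer
  scores, ties make quartile sizes legitimately unequal; the defining
  quantile property (at most 25% strictly below each cut, at least 25% at
  or below it) always holds. A fully degenerate score distribution puts
  everyone in quartile 1 with a warning.
* **Incidence**: 1000 × events / person-years per quartile, with a flag on
  zero-event quartiles (whose rate is 0 with an effectively unbounded CI).
* **Cox models**: statsmodels `PHReg`, Breslow tie handling by default
  (Efron selectable). Quartile analysis fits indicators for quartiles 2–4
  against quartile 1 and reports HR = exp(coef) with Wald 95% CIs; the
  linear-trend p comes from a separate model with the quartile entered as
  an ordinal 1–4 covariate (Wald test). Coefficients beyond |15| are
  treated as monotone likelihood and flagged with an unbounded CI rather
  than silently reported; non-convergence raises. lifelines is used only as
  an independent cross-check in the test suite (with continuous, tie-free
  times, where Breslow and Efron coincide).
* **Age split**: quartiles on the full sample, then a per-quartile 2×2
  (age < 70 vs ≥ 70 × case status) Pearson chi-square, 1 df, no continuity
  correction; quartiles with an empty margin get a null entry.
* **Pipeline**: filter → score → quartiles → incidence → Cox → AUC →
  age split → optional CAIDE comparator, with per-stage logging and
  stage-labelled errors, writing `results.json`, `report.md`,
  `manifest.json` and `run.log` to a run directory. Runs are deterministic
  given the seed recorded in the manifest.

## Numerical and testing choices

Problem sizes in the test suite are chosen to give the checks adequate
power at interactive runtimes: oracle equivalence uses exhaustive
enumeration (exact rationals) at n ≤ 50 and 1-D partial-likelihood
optimisation at ≤ 6 subjects (agreement to 1e-6, restricted to instances
whose likelihood has an identified interior maximiser); parameter recovery
uses 20 cohorts of n = 5000 at β = 0.05; null calibration of the trend test
uses 500 cohorts of n = 600 at β = 0, expecting a 5% ± 2% rejection rate;
marginal fidelity and null-AUC checks use n = 10,000 (3-binomial-SE and
[0.47, 0.53] bands respectively). Random draws are seeded throughout;
hypothesis-based property tests run derandomised.

## Known limitations

Independence of factors is the largest fidelity gap — real risk factors
co-occur, which changes the score distribution and attainable
discrimination. The hazard model is exponential with a single per-point
log-hazard, so it cannot express non-proportional or non-log-linear
dose-response. The CAIDE comparator's continuous inputs (blood pressure,
BMI, cholesterol) are carried as pre-categorised columns; mapping raw
measurements to categories is out of scope, as are multiple imputation,
calibration statistics, competing-risks models and survey re-weighting for
two-phase designs.
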