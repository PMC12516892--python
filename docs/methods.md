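# Methods

`costutility` implements a trial-based cost-utility analysis comparing a
collaborative and stepped care model (CSC) for common mental disorders with
treatment as usual (TAU) in a cluster-randomized primary-care setting, over a
12-month horizon from the societal perspective, together with a synthetic
trial generator that makes every stage testable without patient-level data.
This note documents the model, its assumptions, the tunable parameters, and
the design choices made where the design was genuinely open.

## Health effects

Generic health-related quality of life is described by the EQ-5D-5L: five
dimensions at five levels, 5^5 = 3,125 health states. A value set maps each
profile to a societal utility anchored at 1 (state 11111) and, for the
German-anchored convention used here, −0.661 (state 55555). The shipped value
set is a *placeholder* additive-decrement table with those anchors and a
plausible shape (pain/discomfort and anxiety/depression carry the largest
decrements); the licensed German tariff is not reproduced and loads from CSV
(`ValueSet.from_csv`, columns `dimension, level, decrement`). SF-6D scoring is
likewise licensed; the pipeline accepts precomputed SF-6D indices.

QALYs use the trapezoid rule over the assessments at baseline (T0), 6 months
(T1) and 12 months (T2), each half-year weighted 0.5:

```
QALY = 0.5 · (u_T0 + u_T1)/2 + 0.5 · (u_T1 + u_T2)/2
     = 0.25·u_T0 + 0.5·u_T1 + 0.25·u_T2
```

Utilities are assumed to change linearly between assessments; actual
between-visit durations are ignored (6 months ≡ 0.5 years). Negative
utilities are retained unchanged. EQ-VAS-based QALYs divide each 0–100 score
by 100 first. No discounting is applied on the 12-month horizon.

Secondary effect measures: *response* is a ≥ 50% improvement of the symptom
severity score matching the main diagnosis (PHQ-9 for depressive, GAD-7 for
anxiety, PHQ-15 for somatoform, AUDIT for alcohol-related disorders); it is
undefined at a baseline score of 0 and such records are counted as
non-response at the dataset level (no room for a 50% improvement).
*Remission* uses strict cutoffs: PHQ-9 < 5, GAD-7 < 5, PHQ-15 < 9, and
AUDIT < 4 for females / < 5 for males.

## Costs

All costs are in 2019 euros. Utilization quantities from six-month recall
windows (w0 at T0, w1 at T1, w2 at T2) are valued with standardized unit
costs, each carrying its own price year and inflated by the consumer price
index: `amount × CPI(2019)/CPI(year)`. The shipped unit costs, wages, pack
prices and CPI values are documented placeholders in a realistic order of
magnitude for German care; real analyses supply them via YAML
(`UnitCostTable.from_yaml`).

Eleven categories: inpatient care and rehabilitation (reported merged),
somatic outpatient physician services, outpatient mental health services,
outpatient non-physician services, medical aids, medication (priced per pack
by drug code; unknown codes go to a rejects report rather than being dropped
silently), formal nursing care, informal nursing care (replacement-cost
method: hours × gross hourly wage of a professional substitute), absenteeism
and presenteeism (human capital approach: gross wages; the cost of one day
fully absent is hourly wage × contracted hours/day, default 8), and the
intervention itself. Presenteeism for a window is
`(1 − performance/10) × days_at_work × daily_wage`, with work performance
rated 0–10. Mean intervention costs (default 139€ per patient, SE 0) are
added to intervention-arm 12-month totals.

The six-month windows are assumed to tile the year: w1 + w2 form the
12-month follow-up costs; w0 serves only as the baseline-adjustment
covariate. The societal total is the sum of all categories; the payer
perspective subtracts absenteeism and presenteeism. For the
mental-health-only analysis, categories are tagged at valuation time:
mental-health inpatient days, outpatient mental health services and
psychotropic medication packs feed a memo column that is imputed and
analyzed like any other cost.

Winsorization (sensitivity analysis) caps 12-month totals at the empirical
95th percentile, nearest-rank definition, pooled across arms (per-arm
truncation would make the cap treatment-dependent). Intervention costs are
loaded before winsorization, as part of total-cost construction.

## Missing data

The main strategy is multiple imputation by chained equations with
predictive mean matching (MICE-PMM), assuming missing at random, with
m = 20 imputations. The engine is written in this package so that its
contract is fully specified: variables are visited in order of increasing
missingness; each variable with missing cells is regressed on all other
analysis variables plus the fully observed covariates (including the arm
indicator — imputation is not stratified by arm); regression parameters are
drawn from their approximate normal posterior (type-1 matching: observed
units scored with the posterior mode, missing units with the draw); each
missing cell receives the observed value of one of k = 5 nearest donors by
predicted mean, chosen uniformly. Ten chained iterations per imputation.
Because donors are observed values, imputations never leave a variable's
observed support, and integer scores or category codes stay valid without
special handling. A small ridge term and predictor standardization guard
against collinearity; constant predictors are dropped with a log entry.
Everything is driven by a single `numpy` generator seed (independent spawned
streams per imputation), so results are bit-reproducible.

Imputation operates on the *analysis* scale: utility/symptom scores per
visit and valued category costs per window (missing quantities propagate to
missing costs, never silently zero). Totals and QALYs are derived after
imputation, which preserves the category-additivity identity within every
completed dataset.

Sensitivity strategies: last observation carried forward (forward-only along
T0→T1→T2; missing baselines remain missing and fall back to complete-case
handling) and complete-case filtering with retained/dropped counts.

## Estimation

Costs are nonnegative and right-skewed with a point mass at zero, so the
cost endpoint uses a **two-part model** — logit for any cost, gamma GLM with
log link for positive costs — whenever the zero fraction is at least 5%
(configurable, logged), and a single gamma-log GLM otherwise (isolated zeros
below the threshold are replaced by half the minimum positive value, logged).
Health effects use a gamma-log GLM when strictly positive, a linear model
otherwise (EQ-5D QALYs can be negative), and a logistic model for binary
response/remission.

Adjusted per-arm means come from **recycled predictions** (marginal
standardization): every patient is predicted under both arm assignments and
the predictions averaged; the adjusted difference is CSC − TAU. The
adjustment set is sex, age, occupational status, main diagnosis, inclusion
before the COVID-19 pandemic, number of comorbidities, MCS score, and the
baseline (T0/w0) value of the modeled outcome. When the positive-cost part
has too few observations for the full covariate set (fewer than three per
parameter) or the full fit fails, the gamma part falls back to the
intercept + arm design — a standard concession for sparse categories such as
medical aids or formal care.

The standard error of the adjusted difference resamples practices,
respecting the cluster randomization; the CI is the normal interval
estimate ± 1.96·SE. The default is the **delete-one-practice jackknife**
(grouped jackknife with the (G−1)/G factor). A pairs cluster bootstrap
(within-arm resampling, seeded, with the k/(k−1) finite-cluster variance
rescaling) is available via `se_method="bootstrap"`; in calibration runs at
20 practices per arm its plug-in variance remained measurably
anticonservative for the nonlinear recycled-prediction estimator (about 8%
low against the Monte-Carlo truth, ~91% realized coverage of the nominal
95% interval), while the jackknife tracked the true sampling variance —
hence the jackknife default, which also needs only G refits instead of
hundreds of bootstrap draws. Reported coefficient tables carry robust (HC1 by
default, optionally cluster-robust) covariances. Baseline tables are
compared with F-tests from linear regression for continuous variables and
(multinomial) logistic likelihood-ratio tests for categorical ones; all
p-values are descriptive.

Across imputations, adjusted differences are pooled by **Rubin's rules**
(total variance = within + (1 + 1/m)·between) with Barnard–Rubin
small-sample degrees of freedom; adjusted means are averaged.

## Cost-effectiveness

The ICUR is the ratio of the *unadjusted* difference in mean 12-month total
costs to the unadjusted difference in mean QALYs, with quadrant/dominance
classification and an explicit `undefined` flag when |ΔQALY| < 1e−9.

Uncertainty is summarized by the CEAC from net-benefit regressions. The
individual net monetary benefit at willingness-to-pay λ is
`NB_i(λ) = λ·QALY_i − cost_i`. (The net benefit is deliberately implemented
in this standard orientation; a cost × λ − QALY reading is dimensionally
inconsistent with a euro-scale net benefit.) For each λ on the grid (default
0–50,000€ in 1,000€ steps, 51 points), NB is regressed on the arm indicator
plus the adjustment covariates — including both the baseline total costs and
the baseline effect measure — with heteroskedasticity-robust standard
errors; the arm coefficient is pooled across imputations; the probability of
cost-effectiveness is `1 − p/2` if the pooled coefficient is positive, `p/2`
if negative, and 0.5 at exactly zero (the signed rule does not cover that
boundary). The implementation exploits that NB is linear in λ to fit all
grid points in one pass per imputation.

The cost-effectiveness plane resamples practices within arm (default 1,000
replicates) and recomputes the adjusted incremental cost and QALY per
replicate with linear recycled predictions (within the first imputation by
default, optionally cycling over all), reporting quadrant shares. Its
positive-NB share tracks the CEAC under approximate normality; they are not
numerically identical (clustered bootstrap vs HC1 regression).

## Synthetic trial generator

The generator emulates the structure the analysis assumes; it does not model
the intervention's clinical mechanism (arm effects are injected directly).

* **Design**: two arms of 307/308 patients across 20 practices per arm
  (cluster counts and ICC are assumptions — the emulated study does not
  report them; ICC defaults to 0.02), practice sizes Dirichlet-multinomial
  with every practice recruiting at least one patient, arm assigned at
  practice level.
* **Covariates** per arm mirror the emulated baseline table: sex, age,
  occupational status, main diagnosis (no alcohol-related diagnoses in the
  intervention arm — the subgroup that cannot be analyzed), comorbidities,
  pre-COVID inclusion, recruitment-as-planned, MCS score.
* **Outcomes**: a standard-normal patient severity factor and the practice
  effect drive correlated utilities (loading −), symptom scores (+), MCS (−)
  and costs (+). Each utility/score is a latent normal censored to its
  instrument range; the latent mean is solved numerically so that the
  *censored* mean equals the configured target — the ceiling effect is
  realistic and configured means remain interpretable. Arm-specific
  trajectories reproduce the emulated unadjusted means.
* **Utilization**: per category and window, a hurdle process — Bernoulli
  "any use" × gamma for the positive amount — with a mean-corrected
  lognormal multiplier from the severity factor and practice effect, so the
  unconditional category mean is exactly `p_any × mean_if_positive`. Count
  quantities are rounded stochastically (unbiased). Injected arm effects on
  cost quantities are specified per window on the unconditional mean and
  converted internally to the multiplicative latent shift, making an
  injected effect exact in expectation — which is what makes
  parameter-recovery tests well-posed. Baseline imbalance (older TAU
  patients, costlier CSC patients at baseline) is on by default;
  `TrialConfig.null()` symmetrizes the arms for null-calibration tests.
  Indirect costs apply to employed patients; the not-employed contribute
  zero absenteeism/presenteeism by construction.
* **Missingness** is MAR and blocky: a visit-level dropout event (default
  95% of each rate) masks all outcome and utilization variables of a visit,
  plus independent item nonresponse, with both probabilities logistic in arm
  and baseline MCS and intercepts calibrated by root-finding so each
  variable's *marginal* missingness rate equals its configured value
  exactly in expectation. Default rates rise from ~4–5% at T0 to ~33–34% at
  T2. The complete-data copy is retained alongside the masked copy as the
  oracle for imputation and estimation tests.

What the generator does **not** emulate: informative (MNAR) dropout,
measurement error in self-reported utilization, item-level EQ-5D profiles
(indices are generated directly; profile scoring is exercised separately),
within-category price heterogeneity, and calendar-time effects beyond the
COVID flag. Passing tests therefore demonstrate internal statistical
validity of the pipeline under MAR and the stated data-generating shapes,
not agreement with any real dataset.

## Numerical choices and problem sizes

Tolerances: censored-mean root-finding to 1e−10; missingness calibration to
1e−12; GLM IRLS to 1e−9 with 200 iterations; PMM ridge 1e−6 on standardized
predictors. Ties in donor matching are resolved by `argpartition` order and
a uniform donor draw; all randomness flows from seeded `numpy` generators.

Test and acceptance workloads are sized for a single CPU: simulation suites
use 300 patients per arm, 200 simulated trials for recovery/coverage,
150–200 bootstrap draws per adjusted difference and 600 plane replicates;
the bundled full analysis uses m = 20 imputations with 10 chained
iterations. All sizes are configuration parameters.

## Known limitations

* Unit costs, wages, CPI and the value-set decrements are placeholders;
  results on synthetic data are structurally, not numerically, comparable
  with any published analysis.
* The gamma branch cannot represent exact zeros; below-threshold zeros are
  nudged, which is logged but still an approximation.
* Rubin pooling is applied on the adjusted-difference scale (not to the two
  model parts separately); with strongly non-normal per-imputation
  estimates this is an approximation.
* The CEAC's robust variance is HC1 (matching the stated method of the
  emulated analysis) even though randomization is clustered;
  cluster-robust covariances are available but not the default.
* LOCF and complete-case analyses inherit their well-known biases; they are
  provided as sensitivity analyses only.
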