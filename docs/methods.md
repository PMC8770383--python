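# Methods

This note documents the statistical machinery, the synthetic-data
generator's causal structure, the numerical choices, and the limits of what
the test suite demonstrates.

## 1. Cohort definition

Subjects enter at the **index date**: the second member of the first
*adjacent* pair of eGFR measurements, at most 730 days apart, with the
first ≥ 60 and the second < 60 mL/min/1.73 m². eGFR uses the Japanese
three-variable equation `194 · SCr^-1.094 · age^-0.287` (× 0.739 for
women). Eligibility requires age ≥ 18 at index, ≥ 365 days of pre-index
enrollment, ≥ 730 days of post-index follow-up (waived for subjects who
die), hemoglobin and dipstick proteinuria at the index checkup, no prior
chronic dialysis or kidney transplant, no eGFR < 6 at or before index, and
at least one eGFR within 1,156 days (38 months at 30.43 days/month) after
index. Exclusions are tallied in a fixed precedence order (the order the
rules are listed in `cohort.EXCLUSION_ORDER`) so the filter log is
reproducible; each excluded subject is counted once, under the first rule
it fails. All windows are whole-day constants exposed in `CohortParams`.

Comorbidity lookups use the Quan ICD-10 Charlson algorithms with the
original category weights and the standard hierarchy rules (complicated
diabetes over uncomplicated, metastatic over localized cancer, severe over
mild liver disease). Windows differ by purpose: the CCI score covers the
year before index, CV history the entire pre-index period, and the
malignancy/GI-hemorrhage flags the two pre-index years. The shipped code
map is an illustrative default; analyses of real claims should supply their
own JSON map.

## 2. Exposure and endpoints

Anemia is hemoglobin strictly below the age/sex cutoff (men: 13.5 / 12.0 /
11.0 g/dL for < 60 / 60–69 / ≥ 70 years; women: 11.5 / 10.5 / 10.5), so
status can change through hemoglobin drift *or* an age-band crossing.

The composite renal endpoint fires at the earliest of: a single post-index
eGFR ≤ 70 % of the index value within 3 years (1,095 days); SCr ≥ 2× the
index value; a chronic-dialysis or transplant claim; or any eGFR < 15. Two
readings of the 30 % rule were possible — requiring a confirmed/sustained
decline, or accepting a single qualifying measurement — and the
single-measurement reading was adopted as the simplest; likewise "over 3
years" is read as restricting that component's window rather than anchoring
a comparison measurement. The baseline for both the 30 % rule and the
doubling rule is the index measurement. The composite CV endpoint is the
first post-index claim for unstable angina, MI, heart failure, or a
cerebrovascular event; a death within 30 days of the qualifying claim marks
it fatal (the window is a config key; the source material does not define
"fatal"). Death comes from the enrollment table.

## 3. Weights

**Person-periods.** One row per subject per annual checkup, k = 0 at index.
Exposure is only observed at checkups, so the checkup interval is the
finest observable resolution; event and censoring times keep day precision
inside the final period. Exposure history enters as the single lag
`A_{k-1}` (with `A_{-1} = 0`), optionally augmented with the cumulative
count of exposed periods (off by default).

**Stabilized IPW.** At k = 0, the weight is the ratio of an intercept-only
to a baseline-covariate logistic model's probability of the observed
exposure. For k ≥ 1, pooled logistic models are fitted across all
person-periods: the numerator conditions on exposure history plus a
restricted cubic spline in days since index (Harrell's basis, 5 knots at
the 0.05/0.275/0.50/0.725/0.95 quantiles of observed period-start times);
the denominator adds the covariate columns named in `WeightModelSpec`. The
weight is the within-subject running product of numerator/denominator
probabilities. Reading the weight definition literally, the numerator
contains exposure history and time only; a config flag can add baseline
covariates to the numerator, which is common practice but changes the
estimand's weighting only, not its consistency.

Fitting is Newton–Raphson (statsmodels `Logit`/`MNLogit`); non-convergence
and suspected separation (|coef| > 30) raise with diagnostics rather than
being silently regularized, and non-positive predicted probabilities are a
hard error naming the offending row. Truncation winsorizes at empirical
percentiles with linear interpolation between order statistics (default
1st/99th). The hemoglobin-quintile variant forms sex-specific empirical
quintiles of baseline hemoglobin (category 5 = highest = reference) and
replaces both pooled logistics with multinomial models; with two categories
it reproduces the binary weights exactly.

**Imputation.** Baseline covariates: cohort median (continuous) or mode
(categorical). Time-varying covariates: last observation carried forward,
falling back to the cohort fill. Every imputed cell is logged. **No
censoring weights are used** — deliberately: the weighting scheme
implemented here addresses confounding of exposure, and the generator's
disenrollment process is exposure-independent, so censoring weights would
estimate a correction for a bias that is absent. Informative censoring in
real data is therefore out of scope (see Limitations).

**Stabilized weights and balance.** Mean stabilized weights are ≈ 1 per
period. Note that *stabilized* weights balance confounders conditionally on
the numerator variables (exposure history and time), not marginally:
pooled-over-period SMDs against current exposure stay visibly non-zero even
with perfectly specified models, because anemia prevalence and eGFR both
drift over time. The balance tests therefore assess SMDs within period ×
exposure-history strata, where the < 0.1 criterion applies.

## 4. Survival estimation

The weighted Cox partial likelihood uses **Breslow tie handling**,
consistent with the Breslow baseline-hazard estimator used for the curves
(Efron is available behind a flag for coefficient estimation; its variance
and baseline hazard fall back to the Breslow formulas). Rows are counting
process `(start, stop]` intervals, so time-updated exposure and delayed
entry are native. Newton–Raphson with step-halving converges when the
maximum absolute score < 1e-9 or the relative log-likelihood change
< 1e-10; diverging coefficients (monotone likelihood) raise. The robust
variance is the clustered sandwich over per-subject sums of score
residuals — required because weighting induces within-subject correlation.

The MSM design is current exposure alone; the baseline risk model is
baseline exposure plus baseline age, sex, eGFR, proteinuria, CCI score,
HbA1c, SBP and smoking (plus CV history for the CV outcome). Both a
weighted and a covariate-adjusted unweighted reading of the "baseline risk
model" are supported; the covariate-adjusted unweighted fit is the default
output.

Counterfactual curves: `S(t | regime a) = exp(-Λ̂₀(t) · e^{βa})` with the
weighted Breslow `Λ̂₀`. Confidence bands use a subject-level nonparametric
bootstrap (weights and Cox refitted per replicate; percentile intervals;
default 200 replicates, seeded; replicates with zero events are redrawn),
since no closed-form band is defined for this estimator here. Survival is
reported at years 1, 3 and 6. Weighted Kaplan–Meier curves (weights in
both risk sets and event counts, Greenwood-type intervals via lifelines)
are descriptive companions.

**Fine–Gray.** The sub-distribution hazard model keeps subjects who die in
the risk set after death, down-weighted by `G(t-)/G(s-)` where `G` is the
Kaplan–Meier estimate of the censoring distribution and `s` the death time;
the augmented counting-process rows are fitted with the same weighted Cox
engine. With zero competing events this reduces *exactly* to the
cause-specific model. The clustered sandwich variance on the augmented data
is the practical variance used by standard implementations; the tests
cross-check coefficients against an independent implementation
(`cmprsk::crr`) to 5e-3 on a 400-subject fixture.

**PS matching.** Greedy 1:1 nearest-neighbor on the logit propensity score,
exposed subjects in descending PS order with ties broken by subject id, and
a caliper of 0.25 × SD of the logit PS (the Rosenbaum–Rubin convention; a
flag switches to a raw-logit caliper, since "0.25 caliper" admits both
readings). Unmatched exposed subjects are dropped and counted.

**Incidence.** Rates are `1000 × events / person-years` (person-years =
days/365.25) with exact Poisson intervals by chi-square inversion, which
reproduces printed reference intervals to the displayed precision.

**Slope translation.** `slope_to_hazard` maps an eGFR-slope difference Δ to
a percent hazard change by proportional log-hazard scaling anchored at a
reference point (default: a 0.75 mL/min/1.73 m²/year slope benefit ↔ 27 %
lower hazard): `(1/(1-0.27))^(-Δ/0.75) - 1`. A Δ of −0.7 gives +34 % (and
the closed form at Δ = −0.75 is exactly 1/0.73 − 1 = +36.99 %).

## 5. The synthetic-data generator

The generator emits checkups, claims and enrollment tables with the
pipeline's input schemas, plus a hidden truth table for tests. Defaults are
the study conditions: ~73 % male, age ≈ N(52, 8) in 21–73, index eGFR just
under 60, baseline anemia prevalence 4.2 %, annual checkups (`n_years = 6`),
annual disenrollment 8 %, true hazard ratios 2.6/1.6/2.8
(renal/CV/death), mean eGFR drift −1.0 mL/min/1.73 m²/year with an
anemia-dependent acceleration of −0.7 (the observed slope difference
between anemic and non-anemic subjects). Annual baseline hazards (1.5 %
renal, 2 % CV, 0.8 % death) are set higher than the very low rates seen in
insurance-based cohorts so that simulations of a few thousand subjects
carry enough events for estimator-recovery experiments; they are
per-outcome config fields.

Causal structure per annual period k:

* latent susceptibility `U ~ N(0,1)` accelerates eGFR decline
  (−0.9·U/year) and raises all hazards (coef 0.6·U, scaled by
  `confounding_strength`);
* `eGFR_k = eGFR_{k-1} + drift + accel·A_{k-1} − 0.9·U + noise`;
* `logit P(A_k) = logit(p₀) + 1.8·A_{k-1} + 1.2·(58−eGFR_{k-1})/5 −
  1.0·T_{k-1}` (confounder terms scaled by `confounding_strength`);
* `logit P(T_k) = −3.5 + 2.2·A_{k-1}` (anemia treatment; emitted as
  pharmacy claims);
* hazards are piecewise-constant within periods:
  `λ_o = base_o · exp(β_o·A_k + 0.6·U)`, with exact event days drawn from
  the within-period exponential.

Exposure thus depends on past covariates, covariates depend on past
exposure, and the observed eGFR is a proxy for both the latent risk factor
and the exposure history — the configuration in which covariate adjustment
fails but IPW succeeds. Because exposure depends on the *observed* history
only, the weight denominator conditioning on lagged eGFR, lagged treatment
and lagged anemia is correctly specified. Hemoglobin values are generated
on the correct side of each subject's current age/sex cutoff, so the
downstream classifier reconstructs the true exposure sequence; renal and CV
events surface as dialysis/transplant and CV diagnosis claims, deaths in
the enrollment table. Small fractions of ineligible enrollment patterns
(never-low eGFR, first-eGFR-already-low, prior dialysis) keep the exclusion
tally non-trivial.

Under the defaults (pinned by a design-phase calibration at n = 50,000),
the marginal structural estimate is essentially unbiased for the structural
log hazard ratio, the crude time-dependent Cox is biased upward by ≈ +0.22
on the log scale, and the covariate-adjusted time-dependent Cox is biased
downward by ≈ −0.04 (adjusting for a variable that is both a consequence of
past exposure and a proxy for latent risk). A stronger hazard-side frailty
was rejected: it makes the marginal ("always vs never") hazard ratio
genuinely smaller than the conditional one through risk-set depletion, so
there would be no recoverable single truth.

What the generator does **not** emulate: realistic Japanese claims-coding
breadth (only the codes the pipeline consumes are emitted), seasonality or
checkup non-attendance, measurement error in SCr/Hb, informative
disenrollment, direct hazard effects of treatment, and renal events that
arise from the eGFR trajectory itself (the trajectory carries the
confounding; the event signal travels through claims). Passing tests
therefore demonstrate the *statistical machinery* under a known, favourable
data-generating process — not robustness to the many misspecifications real
claims data offer.

## 6. Monte-Carlo experiment sizes

The recovery study runs 200 replicates of n = 5,000 subjects at a true
hazard ratio of 2.0 (≈ 3,700 retained subjects and ≈ 350 renal events per
replicate), asserting |mean log-HR bias| < 0.05, robust-CI coverage within
[0.90, 0.98], a crude-vs-MSM separation > 0.1 and an adjusted-vs-MSM
separation > 0.01. The null-coverage check of the Cox engine uses 250
replicates of n = 120; the Breslow/KM agreement check uses one null cohort
of n = 2,000; stabilization and balance checks use one cohort of n = 8,000.
These sizes were chosen so Monte-Carlo error is comfortably below each
asserted tolerance.

## 7. Known limitations

* No inverse-probability-of-censoring weights; estimates assume
  exposure-independent censoring.
* The Fine–Gray variance is the clustered sandwich on IPCW-augmented data,
  not the original estimator's exact variance expansion.
* Efron ties support covers coefficients only.
* The simple-imputation scheme (median/mode, LOCF) is a reporting-grade
  placeholder for missingness, not a principled missing-data model; the
  generator's missingness is MCAR by construction.
* `slope_to_hazard` is a deterministic translation of a published
  reference mapping, not an estimate from the data at hand.
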