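# Methods

`cbcprs` models the risk of contralateral breast cancer (CBC) in women
carrying a pathogenic BRCA1 or BRCA2 variant who have already had a first
breast cancer, as a function of a breast-cancer polygenic risk score (PRS).
It implements four layers: PRS scoring, cohort construction with
left-truncated time at risk, stratified cluster-robust survival modelling
with diagnostics and imputation, and a constrained-incidence calculator that
converts a relative hazard per SD into PRS-percentile-specific absolute risk
curves. A synthetic-data generator with known generative parameters makes
every layer testable without access to consortium data.

## PRS scoring

The raw score is `s_j = sum_i w_i g_ij`, with `g_ij` the effect-allele dosage
(0–2, fractional for imputed genotypes) and `w_i` a per-allele log odds
ratio. Three flavours (overall, ER-positive, ER-negative) share variants but
use different weights. Source dosages are oriented to the panel's effect
allele before scoring: matching coded allele passes through, the opposite
allele maps `d -> 2 - d`, mismatched allele pairs are dropped, and
strand-ambiguous pairs (A/T, C/G) are dropped when the source allele
frequency differs from the panel frequency by more than 0.2 — the standard
heuristic, since strand cannot be resolved from the alleles alone. Missing
dosages are mean-imputed at `2p` (the HWE expectation); subjects with more
than 20% of panel variants imputed are flagged.

Standardization follows a two-population contract: scores are centred on the
mean of the full analysis cohort (cases and non-cases alike) and divided by
an externally supplied reference SD, so hazard ratios are per SD of the
reference population, not of the selected cohort. The reference SD is a
required input with no default — it is a property of the weight panel and
reference sample; the synthetic panels are constructed with unit variance
(`sum_i 2 p_i (1-p_i) w_i^2 = 1`), so tests supply 1.0.

## Cohort and time at risk

Time is measured in years since the first breast cancer (BC1), with delayed
entry fixed at 1.0 year: a CBC within one year of BC1 is treated as
synchronous disease and excludes the subject rather than counting as an
event. Subjects are also excluded when the baseline ascertainment age is
missing, when BC1 occurred less than a year before baseline, or when the
first tumour was known metastatic (unknown metastatic status is retained).
Follow-up censors at the earliest of baseline age, risk-reducing
contralateral mastectomy and death; a sensitivity option additionally
censors at distant relapse, dropping subjects whose relapse precedes entry.
Event definitions: any metachronous CBC (invasive or in situ); invasive
only (in situ censors at diagnosis); and ER-specific definitions in which a
CBC of the other or unknown ER status censors at its diagnosis age.
Synchronicity uses the age difference when exact dates are unavailable.
Every input subject ends up in exactly one of three sets — interval-bearing,
excluded-with-reason, dropped-for-no-time-at-risk — and eligibility is
idempotent.

Birth-cohort quartiles are computed from the analysis cohort's observed
birth-year distribution with linear-interpolation quantiles; the edges are
recorded in the interval table's metadata.

## Survival models

The association model is a Cox partial likelihood with delayed entry,
stratified by country, adjusted for birth-cohort quartiles, with a cluster
sandwich variance over family identifiers (related women appear in the same
cluster). Fitting is delegated to lifelines (Efron tie handling). Key
design choices:

* **Percentile bands.** Categories are cut at the 5/10/20/40/60/80/90/95
  percentiles of the PRS among unilateral cases, assignment is half-open
  `[lower, upper)`, and the 40–60 band is the reference. The companion
  `predict_band_hrs` computes the band hazard ratios implied by a continuous
  per-SD log HR `b` under a standard-normal PRS in closed form,
  `E[e^{bz} | z in B] = e^{b^2/2} (Phi(b_hi - b) - Phi(b_lo - b)) /
  (Phi(b_hi) - Phi(b_lo))`, each relative to the reference band; the
  categorical fit should track this curve when the continuous model holds,
  which is verified on large synthetic cohorts.
* **Age interaction.** The interaction model includes `z` and
  `z * age_bc1` with uncentred age, so the main effect is the per-SD log HR
  extrapolated to age zero. A centring convention changes the main effect's
  meaning, not the model; uncentred age matches the reporting convention of
  a main effect plus per-year interaction. Age-group refits use <40,
  [40, 50), [50, inf) — 40 belongs to the middle group and 50 to the oldest.
* **Proportional hazards.** lifelines cannot compute Schoenfeld residuals
  under delayed entry, so the package computes them directly: for each
  event, the covariate vector minus the risk-weighted covariate mean over
  the stratum risk set `{entry < t <= exit}`. The test statistic is the
  Grambsch–Therneau form — scaled residuals (`d * r V`, with `V` the naive
  inverse information) correlated against Kaplan–Meier-transformed time
  (left-truncated KM of the event distribution), referred to chi-squared
  with 1 df. This approximation is known to run conservative at small event
  counts; in simulations its null p-values are uniform (KS test) from
  roughly 300 events upward, which is where the calibration suite operates.
* **Linearity.** Restricted cubic splines (Harrell parameterisation) with
  three knots at the 10/50/90 percentiles of `z`; a likelihood-ratio test of
  the nonlinear term against the linear model, using non-robust likelihoods.
* **Concordance.** Harrell's C stratified by country and honouring delayed
  entry: a pair is comparable only if the non-failing member is in the risk
  set at the failure time. Counting uses a Fenwick tree over score ranks
  with dynamic activation/deactivation, `O(n log n)` per stratum; score ties
  count one half, tied event times are not comparable. Confidence intervals
  come from a cluster bootstrap over families (default 1,000 resamples,
  seed-controlled); the implementation agrees exactly with
  scikit-survival's concordance on plain right-censored data and, for
  uncensored exponential data, with the closed-form pair probability
  `E[1 / (1 + e^{-b |z_1 - z_2|})]`.
* **Kaplan–Meier.** Cumulative risk `1 - S(t)` with delayed entry and
  Greenwood-based confidence bands, via lifelines.

No multiple-testing adjustment is applied (two-sided alpha = 0.05
throughout).

## Missing data

Covariates are imputed by chained equations: visit order ascending in
missingness, logistic models for binary variables, proportional-odds models
for ordered categoricals, and linear regression with predictive-mean
matching (5 donors) for continuous variables. The event indicator and log
follow-up time are always predictors, the standard practice when imputing
covariates destined for a survival model. Draws from each conditional
model's asymptotic parameter posterior make the imputations proper; a
marginal-draw fallback covers non-converging conditional fits (e.g.
separation). Defaults: m = 10 completed datasets, 10 iterations. ER-specific
analyses impute the CBC's ER status per completed dataset, apply
alternative-ER censoring inside each dataset, fit, and pool. Pooling
reports the arithmetic mean of coefficients as the point estimate and
additionally the Rubin decomposition (within + (1 + 1/m) · between) for
interval construction; the two are labelled separately because the mean
rule alone understates uncertainty.

## Constrained-incidence absolute risk

Given an external marginal CBC incidence schedule `lambda_m(t)` (per year,
by age group at first diagnosis) and an effective per-SD log hazard ratio
`beta_eff = beta + gamma * age_bc1`, the baseline hazard is solved on a
uniform grid by forward recursion:

    lambda_0(t) = lambda_m(t) * sum_k w_k S_k(t)
                              / sum_k w_k S_k(t) e^{beta_eff z_k}
    S_k(t + dt) = S_k(t) * exp(-lambda_0(t) e^{beta_eff z_k} dt),  S_k(0) = 1

with `{z_k, w_k}` discretising the standard-normal PRS density — by default
99 equal-weight percentile nodes `z_k = Phi^{-1}((k - 1/2)/99)`;
Gauss–Hermite nodes are available as an accuracy cross-check. Percentile
curves are `F(t | z_p) = 1 - exp(-sum lambda_0 e^{beta_eff z_p} dt)`.

In the continuous-time limit the density-weighted average survival obeys
`dS-bar/dt = -lambda_m S-bar`, so the averaged cumulative risk reproduces
the marginal schedule exactly; the discrete recursion is first-order in
`dt`, and `marginal_conservation_check` exposes the deviation (about 20x
smaller at dt = 0.05 than at dt = 1, and ≤ 1e-3 at dt = 0.05 over a 20-year
horizon at moderate effect sizes). Defaults: dt = 0.1 year for production
curves, 0.05 for conservation checks; schedules coarser than dt are refined
stepwise-constant. Degenerate single-node input (w = 1, z = 0) reproduces
the marginal curve for any effect size. The risk clock starts at the first
breast cancer; a one-year entry offset applies only when comparing against
cohort Kaplan–Meier output.

## Synthetic data

The generator emulates a clinic-ascertained retrospective carrier cohort.
Its defaults are the study conditions the rest of the package is tested
under:

| parameter | default | rationale |
|---|---|---|
| subjects / event fraction | 6,591 / 0.213 | BRCA1-scale cohort with ~1,402 events |
| true HR per SD | 1.12 | headline BRCA1 ER-negative association |
| baseline hazard | 0.032 / year, constant from entry | gives a ~25% 10-year cumulative risk |
| age at BC1 | truncated normal, mean 41.8, SD 10, on [18, 85] | observed mean; SD chosen to span the reported 19–82 range |
| baseline lag | 1 + lognormal(log 6, 0.8) years | median follow-up ~6 years from entry |
| countries | 5, equal weights | enough strata to exercise stratification |
| family sizes | 90% / 8% / 2% for 1/2/3 | <10% multi-member clusters, as in consortium family data |
| mastectomy / death | 3% / 0.8% | reported bilateral-mastectomy and death counts |
| in situ CBC fraction | 10% | reported invasiveness split |
| covariate missingness | e.g. ER of BC1 56%, CBC ER 61% | magnitudes of the unknown categories |

Genotypes: founders under Hardy–Weinberg at the panel frequencies; families
of size 2–3 are full sibships built from explicit parental genotypes with
Mendelian transmission, so within-family genotype correlation (0.5 for sibs)
is genuine rather than a covariance shortcut, and cluster-robust variance
behaviour is exercised honestly. Weight panels draw frequencies uniform on
(0.01, 0.5) and rescale weights to an exact target raw-score variance. Event
times come from the piecewise-exponential hazard
`lambda_b(t) exp((beta + gamma * age_bc1) z)` by inversion, with an
overflow guard on the linear predictor; when calibration is enabled the
baseline is rescaled so the expected event fraction under the drawn
censoring times equals the target. Missingness is MCAR by default, with a
country-tilted missing-at-random option to stress the imputer; the original
values are returned in a truth channel for recovery tests. All randomness
descends from one master seed through fixed-purpose child seeds, so output
is byte-identical under a repeated seed.

What the generator does **not** model: linkage disequilibrium between
variants, genotype-imputation uncertainty beyond optional fractional dosage
noise, referral-based ascertainment (families enriched for early onset or
family history), calendar-time effects, or competing mortality. Passing
tests therefore demonstrate the statistical machinery is correct under the
stated generative model, not that real-cohort estimates are free of
selection effects.

## Problem sizes and numerical choices

Recovery tests run 20 replicates at the two cohort scales (6,591 and 4,208
subjects; 3,154 for the young-onset subgroup), comparing the geometric-mean
fitted HR per SD against the generative value within three Monte-Carlo
standard errors. Null-calibration suites use 200 replicates of 1,500
subjects (~315 events), the size at which the PH approximation is
calibrated. The large-sample consistency check between categorical and
continuous fits uses one 50,000-subject cohort. Conservation checks use
dt = 0.05 with 99 nodes. Quantiles everywhere use the linear-interpolation
convention; ties in banding are resolved by stable ordering. Duplicating a
dataset leaves the cluster-robust SE and (up to Efron tie corrections) the
point estimate unchanged while shrinking the naive SE by `1/sqrt(2)` — the
sandwich algebra check.

## Known limitations

* The Cox layer has no frailty or time-varying coefficients; the PH test is
  diagnostic only.
* ER-specific analyses censor (rather than compete) the alternative ER
  status; no Fine–Gray estimation.
* The absolute-risk layer ignores competing mortality, so long-horizon
  curves overstate lifetime CBC probability at older ages.
* The interaction model evaluates `beta_eff` with uncentred age; at ages
  where `beta + gamma * age < 0` the percentile ordering of risk curves
  inverts. A centring offset is exposed for users who prefer an age-centred
  main effect.
* Imputation assumes missing-at-random given the included predictors; no
  MNAR sensitivity analysis is provided.
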