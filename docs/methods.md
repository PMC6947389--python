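# Methods

## IOM compliance classification

WHO pre-pregnancy BMI categories use half-open intervals with the
conventional boundaries (18.5 → normal, 25 → overweight, 30 → obese).
Trimesters are defined on completed gestational weeks: T1 ≤ 13, T2 14–27,
T3 ≥ 28.

The IOM 2009 guidance states a *total* recommended gain per category.  How
mid-pregnancy compliance against a total window should be judged is a
genuine design choice, and the package records the mode used in every
output:

* **interpolation** (default): each bound is interpolated linearly between
  a first-trimester anchor of 0.5–2 kg at week 13 and the recommended total
  at week 40.  This mode uses only the published total windows and recovers
  them exactly at term, which is why it is the default.
* **rate**: each bound grows from the same anchor at the IOM second/third
  trimester weekly rates (0.44–0.58, 0.35–0.50, 0.23–0.33, 0.17–0.27
  kg/week for the four categories).

Window bounds are treated as *inclusive*: a gain exactly on a bound is
"within guidelines" (we read recommendation ranges as closed intervals).
When several weighings fall in one trimester the latest is used, being
closest to the projection horizon.  A record without pre-pregnancy weight,
BMI or a weighing in the requested trimester raises an explicit exclusion,
which the pipeline accounts for before any table is built.

The GDM screening rule is the two-step 50 g challenge / 75 g OGTT
algorithm: challenge ≥ 10.3 mmol/L is diagnostic; 7.8–10.2 mmol/L requires
the OGTT, positive if any of the 0/1/2 h values reaches 5.3/10.6/9.0
mmol/L.  A challenge in the confirmation zone without OGTT values returns
an *indeterminate* status rather than a negative.

## Group-based trajectory model

Weight (kg, absolute by default; gain mode available) over gestational
weeks is a finite Gaussian mixture of polynomial mean curves with either a
shared or per-group residual SD.  Defaults: linear curves (order 1), shared
σ (fewer degeneracies), J swept over 1–3 in the pipeline and selectable up
to any range via `select_model`.

Estimation is multi-start EM:

* initialisation: k-means (seeded) on standardised per-subject OLS
  (intercept, slope) summaries for the first start, random hard
  assignments for the rest; 10 restarts by default (4 in the pipeline);
* E-step in log space with `logsumexp`; M-step by responsibility-weighted
  polynomial least squares, π as mean responsibility, σ from weighted
  residuals with a 1e-6 kg floor;
* convergence at relative log-likelihood change < 1e-8, max 500
  iterations; the log-likelihood history is retained and is non-decreasing
  by construction (asserted in tests);
* an optional quasi-Newton (L-BFGS) polish refines the winning EM solution
  on the unconstrained parameterisation (softmax shares, log σ) and is
  kept only if it improves the log-likelihood.

Non-convergence and essentially-empty groups (π_j < 1/n) are flagged on
the fit, never silent; model selection skips degenerate candidates and
fails loudly (with the sweep table attached) if none remain.

BIC is computed as −2 logL + k log(n_subjects), *minimised*, with
k = (J−1) + J·(order+1) + (1 or J) free parameters — an equivalent ranking
to the maximised form some trajectory software prints.  Label switching is
resolved by ordering groups on the fitted mean at week 20 (ascending), so
reported group A is always the lightest trajectory.

Slope standard errors condition on the final posterior weights
(σ_j²(XᵀW_jX)⁻¹, the pseudo-class approximation); they understate mixture
uncertainty slightly when groups overlap, which is acceptable for the
well-separated fits the adequacy diagnostics accept.  Slopes are reported
per modelling time unit (kg/week by default) without claiming equivalence
to any other time coding.

## Relative-risk estimation

Modified Poisson regression: log-link Poisson GLM on the 0/1 outcome,
coefficients exponentiated to RRs, HC0 sandwich variance (the standard
choice for this estimator; the variant name is recorded in every
estimate).  Wald CIs and p-values on the log scale.  Missing data are
handled complete-case per model with the analysed n reported, since
cohort tables routinely have different denominators per outcome.
The saturated two-level no-covariate model reproduces the closed-form
proportion ratio to numerical precision, which the tests assert.

Covariate policy: age, parity, smoking, chronic hypertension, diploma,
income, pre-existing diabetes for every outcome except GDM, whose model
drops pre-existing diabetes (diagnosed diabetes would be circular there).

## Supporting statistics

The trend across ordered exposure categories is the Cochran–Armitage test
with equally spaced scores — the standard reading of a "continuity across
ordered groups" p-value; this is an assumption, documented here, not a
claim about any particular software's implementation.  Continuous group
comparisons gate on Shapiro–Wilk (every group) and Bartlett at α = 0.05:
both pass → ANOVA with Tukey–Kramer; otherwise Kruskal–Wallis with Dunn's
rank test (Bonferroni), which is also the fallback (flagged) when a
constant-valued group makes Bartlett undefined.  Categorical comparisons
use chi-squared without continuity correction when all expected counts are
≥ 5, Fisher's exact for sparse 2×2 tables; sparse tables larger than 2×2
fall back to chi-squared with a `small_expected` flag rather than an
r×k exact test.  The Marascuillo procedure flags pairs whose absolute
proportion difference exceeds
√(χ²_{k−1,0.95}) · √(p̂_i(1−p̂_i)/n_i + p̂_j(1−p̂_j)/n_j).

## Synthetic cohort generator

The generator emulates the *structure* of a large single-centre pregnancy
cohort so that every stage of the analysis is testable without data
access:

* three latent groups with shares 58.3/32.4/9.3 % and pre-pregnancy BMI
  ~ Normal(21.2, 2.2), (26.3, 3.1), (35.6, 5.0) kg/m²; height
  ~ Normal(1.64, 0.065) m; pre-pregnancy weight = BMI·height²;
* absolute weight anchored at the pre-pregnancy weight at week 0, plus a
  group-level quadratic mean-gain curve (gain accelerating after T1,
  reaching the group total at week 34), scaled per woman by a Gaussian
  frailty (CV 0.28/0.25/0.40) and observed with 1 kg visit noise at one
  weighing per trimester (weeks ~10/22/34, ±2 weeks, rounded to completed
  weeks);
* group gain totals at week 34 of 12.0/14.5/9.0 kg.  These were calibrated
  once so that, under the interpolation projection, the third-trimester
  compliance mix lands at the ~13 % below / ~54–57 % above pattern large
  cohorts report.  Under this projection rule the published per-profile
  gain medians and the published compliance mix cannot both be reproduced
  exactly; the generator prioritises the compliance mix while preserving
  the B > A > C ordering of gains;
* outcomes: GDM, HDP, caesarean and hypoglycemia are Bernoulli draws from
  log-linear models P = exp(β₀ + Σβx) (clipped to [0,1] with a warning);
  SGA and LGA are drawn as one three-way categorical (so they are mutually
  exclusive with exactly the modelled marginals) and birth weight is then
  sampled from the matching truncated region of the reference
  distribution — Normal, mean 3400 g at 40 weeks, 180 g/week, SD 450 g —
  keeping flags and percentiles exactly consistent.  Macrosomia is always
  derived as birth weight strictly above 4000 g.  Default exposure
  coefficients are the third-trimester compliance labels with log-RRs set
  to round published adjusted estimates (e.g. 2.26 for LGA above
  guidelines), plus modest covariate effects; covariate prevalences differ
  by latent group, which induces real confounding for the adjustment
  machinery to remove.

What the generator does *not* emulate: outcome–outcome dependence beyond
the SGA/LGA exclusivity, direct BMI effects on outcomes beyond those
mediated by exposure and measured covariates (a deliberate choice — any
direct effect would be an unmeasured confounder of the compliance
exposure, breaking the known-truth recovery experiments), clinical fetal
growth curves, twin pregnancies, or missing-data patterns.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to real-data pathologies.

## Problem sizes and tolerances

Recovery experiments use n = 2000 subjects × 4 time points × 20 replicates
for trajectory models (shares within ±0.03, posteriors > 0.90, BIC
selection rate ≥ 19/20 over a J = 1–4 sweep), 200 small replicates for CI
coverage (accepted within [90 %, 99 %]), and 20 full-size (n = 6551)
cohorts for adjusted-RR recovery (CI coverage of the generating 2.26
LGA RR in ≥ 18/20).  The likelihood oracle is exact enumeration on
5-subject instances, agreed to 1e-10.  These sizes keep the whole suite
and the acceptance script in the minutes range on a single CPU while
leaving the stochastic assertions far from their thresholds.

## Known limitations

* The projection of total IOM windows to mid-pregnancy is a documented
  modelling choice; different cohorts/authors use different rules, so
  absolute compliance percentages are rule-dependent.
* Single-outcome trajectories only: no joint multi-trajectory modelling,
  censored/zero-inflated variants, or covariates on group membership.
* No multiple imputation or standardisation; complete-case estimates only.
* The Dunn post-hoc uses Bonferroni adjustment, which is conservative for
  many groups.
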