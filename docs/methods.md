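# Methods

## Scope and model

`costmiss` is a Monte-Carlo benchmark for estimators of mean monthly societal
cost under missing data. All quantities are EUR/month at the patient level;
the estimand throughout is the mean cost of a cost-complete baseline cohort
("the true mean"), recomputed from the input cohort on every run rather than
fixed as a constant.

## Synthetic cohort

The generator emulates the baseline of a large three-country observational
Alzheimer's disease cohort (community-dwelling patients with MMSE ≤ 26 and an
informal caregiver).

**Total cost.** Lognormal, moment-matched to a target mean and SD. Defaults:
mean EUR 2101; SD EUR 2381.4, derived from the published 95% CI
(half-width 121) as `121/1.96 × √1488` — a normal-theory CI is assumed; if
the original interval were bootstrap-based the implied SD would differ
modestly. Cost data are canonically right-skewed, and a lognormal matched to
these two moments reproduces the published MNAR complete-case bias profile to
within ~2 percentage points, which is the property the surrogate needs.

**Covariates.** Age ~ truncated normal (mean 77.6, SD 7.66, ≥ 55); MMSE and
ADCS-ADL integer truncated normals (MMSE mean 17.4, SD 5.92 from the printed
CI; ADL mean 40, SD 14 — plausible mid-range values for this population, not
published calibration targets); 54.8% female; 35% of caregivers working.

**Caregiver time.** Total monthly hours lognormal with σ = 1.1 and μ solved
so that P(hours > 470) = 0.15 — this makes the deterministic
institutionalisation threshold rule (below) hit its target rate by
construction. Hours are capped at 24 h/day × 30.4 days (the cap is
configurable; published analyses mention capping to allow for sleep without
stating the value) and split into basic-ADL / instrumental-ADL / supervision
shares by a Dirichlet(2.5, 2.5, 5) draw, putting roughly half of caregiver
time into supervision so that including supervision raises informal-care
costs substantially.

**Joint structure.** A Gaussian copula links cost, total caregiver hours,
MMSE, ADCS-ADL and age. Published sources state directions (costs and
caregiver time rise as cognition and function worsen) but no magnitudes;
defaults are cost–hours +0.6, cost–MMSE −0.35, cost–ADL −0.45, hours–MMSE
−0.30, hours–ADL −0.40, MMSE–ADL +0.50, age–cost +0.10, all configurable,
validated positive semi-definite.

**Component costs.** The informal-care component is composed from hours by
the base-case costing rule at the generator's own unit costs (working
EUR 9/h, non-working EUR 5/h — chosen so informal care averages ~40–45% of
total cost, its plausible share); the three remaining components split the
residual 50/33/17. Where the drawn informal cost would exceed the drawn
total (~10–13% of records, a consequence of drawing the total directly so
its calibration stays exact), informal care is capped at the total and the
other components are zero; the components therefore always sum exactly to
the total, at the price of a distorted component split in the capped tail.

**Baseline incompleteness.** 0.6% of records, completely at random, with all
cost fields blanked; the analysis set is the cost-complete remainder
(1488 of 1497 at defaults).

**What the generator does not emulate.** Country strata, per-visit cost
trajectories, realistic component-cost distributions, integer-valued hours,
and any covariate the copula omits. Passing tests show the estimators behave
correctly for a right-skewed cost law with this dependence structure — not
that the synthetic data match any real dataset cell-for-cell.

## Missingness mechanisms

MCAR draws exactly `round(volume × n)` patients uniformly. MAR deletes the
`round(volume × n)` patients with the lowest combined severity score
z(MMSE) + z(ADCS-ADL) (worst cognition/function), a deterministic threshold
rule whose cut is implicitly solved to hit the volume exactly. MNAR deletes
the top-cost patients the same way. Ties at a threshold are broken by stable
patient order and logged.

The mixed-reason dropout pattern assigns, in order: institutionalised (15%),
died (6%), lost to follow-up (12%) — 33% in total. Institutionalisation is
either MAR (logistic score on MMSE, ADCS-ADL, caregiver hours; default
coefficients −0.08, −0.03, +0.002 per unit — the named covariates are
published, the equation is not, so the coefficients are package defaults and
recorded in run metadata) or MNAR (caregiver time > 470 h/month, with
caregiver time then excluded from the imputation models). Death uses a
logistic score on MMSE, ADCS-ADL and age (−0.05, −0.02, +0.05). The
logistic channels select **exactly** `round(rate × n)` patients by weighted
sampling without replacement (Gumbel-top-k on the scores): realised channel
frequencies equal their targets while higher-risk patients remain more
likely to be chosen; an intercept is unnecessary because it cancels under
top-k selection. The assignment order prevents double-assignment; no order
is published, and the marginal rates are unaffected by it.

## Estimators

- **Complete case**: mean and SE of observed costs; normal-theory 95% CI.
- **Grouped means**: missing costs replaced by the observed mean of the
  patient's MMSE severity stratum (mild 21–26, moderate 15–20, moderately
  severe/severe < 15); an empty stratum falls back to the overall observed
  mean with a warning.
- **Fixed cost**: missing costs with a chosen dropout reason set to a
  constant (default EUR 2940/month, a published institutionalisation cost).
- **MI by data augmentation**: the joint (cost, covariates) vector is
  modelled multivariate normal. EM (tolerance 1e-6 relative log-likelihood,
  cap 500 iterations; the observed-data log-likelihood is non-decreasing)
  provides starting values. The chain alternates the I-step (missing cells ~
  conditional normal given observed cells and current (μ, Σ), solved per
  missingness pattern) and the P-step (Σ ~ inverse-Wishart(n−1, S),
  μ | Σ ~ N(ȳ, Σ/n) — the Jeffreys-prior posterior). Defaults: burn-in
  2000, one imputation every 500 states, m = 5 from a single chain (m was
  not published; 5 is the era-standard default). A parallel-chains option
  (m chains, one imputation each) matches the alternative reading of
  "multiple chains". Imputed costs stay on the raw EUR scale and may be
  negative under the normal model; `floor_at_zero` clips imputed (never
  observed) cells and is off by default. Non-positive-definite covariance
  draws are retried with logged jitter.
- **Rubin pooling**: Q̄ = mean of the m means; T = W̄ + (1 + 1/m)B;
  df classic, or Barnard–Rubin when the complete sample size is known
  (B = 0 gives infinite df). MI CIs use the t quantile at the pooled df.
- **Combination scenarios**: Scenario A — lost-to-follow-up by grouped
  means; institutionalised by MI on (MMSE, ADCS-ADL, caregiver hours);
  died by MI on (age, MMSE, ADCS-ADL). Scenario B — as A with
  institutionalised set to the fixed cost. Deterministic fills happen first;
  each MI channel is fitted on observed rows plus that channel's missing
  rows, and the j-th draws of all channels are assembled into the j-th
  completed cohort before pooling. The **single**-MI method's default
  covariates are (MMSE, ADCS-ADL, age) — deliberately excluding caregiver
  time, so the MNAR institutionalisation flavour genuinely is MNAR for it.

## Evaluation protocol

Each cell bootstrap-resamples the analysis set with replacement to its own
size, re-derives the mask on the resample (thresholds re-solved, so volumes
stay exact; the alternative — freezing thresholds from the original cohort —
is not used), applies the estimator and records (mean, SE, CI). One master
seed spawns an independent substream per iteration. Defaults: 1000
iterations per cell; examples and the heavier property tests use 30–50
iterations with shortened MI chains (burn-in 100, thin 25), which leaves
Monte-Carlo noise well below the effect sizes those checks assert.

The six summary measures follow the standard simulation-study definitions;
relative bias is 100 × (estimate − true)/true, negative meaning
underestimation. SSE is the SD of iteration means, SEE the mean of iteration
SEs, and their ratio diagnoses SE estimation adequacy.

The from-scratch benchmark script spreads its 1000 bootstrap iterations for
each bias quantity over 10 independently generated cohorts (100 each) and
averages the per-cohort relative biases: a single n = 1488 lognormal cohort
carries ~1.2 percentage points of cohort-level noise in the trimmed-mean
ratio, and averaging over cohort replicates shrinks surrogate noise about
threefold without changing the estimand.

## Caregiver-time costing

Base case: costed hours are basic + instrumental ADL (supervision excluded),
capped; the informal-care cost is max(costed hours × u, missed-work hours ×
u) with u an opportunity cost differing by working status. Variants:
include supervision; replacement valuation (one unit cost for everyone,
supervision included — matching how the single-unit-cost alternative is
conventionally defined); cost working caregivers' time only. Default unit
costs (20/10/15 EUR/h) are placeholders, not study-derived wages — set them
explicitly for substantive use. Published reports of the supervision effect
differ between +43% and +46% in different sections; this package asserts
only the direction (supervision never decreases, working-only never
increases a record's cost), since the magnitudes are data-dependent.

## Known limitations

- The truncated-mean oracle and the MNAR bias surrogate assume the lognormal
  cost law; real cost data with a different tail would shift the MNAR bias
  profile by a few points.
- MI assumes joint normality; on the skewed cohort it removes most but not
  all MAR bias (linear conditional means under-correct a log-linear
  relationship), consistent with the published residual biases.
- Item-level (per-component) imputation, longitudinal/repeated-measures
  modelling, predictive-mean-matching and propensity-score MI are out of
  scope.
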