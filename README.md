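# costmiss

Simulation toolkit for studying **how the handling of missing cost data
biases cost-of-illness estimates** in long-follow-up observational studies of
Alzheimer's disease and similar chronic conditions — and for putting that
bias in context against a larger one: the rules chosen for valuing informal
caregiver time.

Prospective dementia cohorts lose roughly a third of their patients over 18
months, to institutionalisation, death and loss to follow-up. Each dropout
reason implies a different missing-data mechanism for the patient's monthly
societal cost *Y* (patient health care + patient social care + caregiver
health care + informal care, EUR/month):

- **MCAR** — missingness unrelated to anything: P(R=0) constant;
- **MAR** — missingness driven by observed covariates *X* (cognition MMSE,
  function ADCS-ADL): P(R=0 | Y, X) = P(R=0 | X);
- **MNAR** — missingness driven by the unobserved cost itself.

`costmiss` generates calibrated synthetic baseline cohorts, imposes each
mechanism (plus a realistic mixed-reason dropout pattern) at 10–40% volume,
estimates the mean cost by complete-case analysis, severity-group means,
fixed-cost substitution, **multiple imputation via multivariate-normal data
augmentation** (EM starting values; Jeffreys prior; I-step draws missing
cells from their conditional normal, P-step draws (μ, Σ) from the posterior;
2000-iteration burn-in, 500 between imputations), and **reason-tailored
combinations** of these, then scores every (mechanism × volume × method)
cell over bootstrap resamples with six outcome measures: mean cost, absolute
and relative bias, sampling standard error (SSE), mean standard-error
estimate (SEE), SEE/SSE, and 95% CI coverage probability. The *m* completed
datasets are pooled by Rubin's rules, T = W̄ + (1 + 1/m)B, with
Barnard–Rubin degrees of freedom.

## Worked example

```python
from costmiss import MIConfig, analysis_set, generate_cohort
from costmiss.evaluation import MechanismSpec, MethodSpec, run_grid
from costmiss.report import format_summary_table

cohort = analysis_set(generate_cohort(seed=1))   # 1488 cost-complete dyads
table = run_grid(
    cohort,
    [MechanismSpec(k, volume=0.3) for k in ("mcar", "mar", "mnar")],
    [MethodSpec("complete_case"),
     MethodSpec("mi", mi_config=MIConfig(burn_in=100, thin=25))],
    n_iter=50, seed=7,
)
print(format_summary_table(table))
```

prints (seed 1, 50 iterations):

```
       method  mechanism  true_mean  mean_cost  absolute_bias  relative_bias_pct  sse  see  see_sse_ratio  coverage_probability
-------------  ---------  ---------  ---------  -------------  -----------------  ---  ---  -------------  --------------------
complete_case   MCAR@30%       2002       2013             11                0.5   71   75           1.06                  0.96
           mi   MCAR@30%       2002       2008              6                0.3   75   76           1.00                  0.96
complete_case    MAR@30%       2002       1547           -456              -22.8   51   48           0.95                  0.00
           mi    MAR@30%       2002       1854           -148               -7.4   80   63           0.79                  0.42
complete_case   MNAR@30%       2002        995          -1007              -50.3   25   16           0.65                  0.00
           mi   MNAR@30%       2002       1039           -964              -48.1   27   17           0.63                  0.00
```

Reading: under MCAR both estimators are unbiased and cover at ~95%; under
MAR the MI model, which sees the predictors of missingness, removes most of
the −23% complete-case bias; under MNAR (top-cost deletion) *every* method
underestimates by ~50% and coverage collapses to zero — when the trigger for
missingness is the unobserved cost itself, imputation cannot recover it.
The `examples/` scripts walk through cohort generation, this mechanism grid,
the reason-tailored combination scenarios, and the caregiver-time costing
variants; a thin CLI (`costmiss cohort|mask|simulate|cost-variants|report`)
wraps the same calls for shell use.

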