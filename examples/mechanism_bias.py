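"""Bias of complete-case analysis vs multiple imputation by missing-data mechanism.

Reproduces the core qualitative result of the benchmark at desk scale: under
MCAR both estimators are unbiased; under MAR the MI model (which sees the
predictors of missingness) corrects most of the complete-case bias; under
MNAR top-cost deletion every method underestimates and the bias grows with
the volume of missing data.
"""

from costmiss import MIConfig, analysis_set, generate_cohort
from costmiss.evaluation import MechanismSpec, MethodSpec, run_grid
from costmiss.report import format_summary_table

cohort = analysis_set(generate_cohort(seed=1))

mechanisms = [MechanismSpec(kind, volume=v)
              for kind in ("mcar", "mar", "mnar") for v in (0.1, 0.3)]
methods = [
    MethodSpec("complete_case"),
    # shortened chain for a quick demonstration; defaults are 2000/500
    MethodSpec("mi", mi_config=MIConfig(burn_in=100, thin=25)),
]

table = run_grid(cohort, mechanisms, methods, n_iter=50, seed=7)
print(format_summary_table(table))

# Read the relative_bias_pct column: near 0 for MCAR (both methods), strongly
# negative for complete cases under MAR but small for MI, and large negative
# for both under MNAR — missingness driven by the unobserved cost itself
# cannot be fixed by imputation.  CP is the fraction of 95% CIs covering the
# complete-sample mean; it collapses whenever the bias is large.
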