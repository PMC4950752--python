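"""Reason-tailored combination imputation on mixed-reason dropout patterns.

Emulates 18-month dropout (15% institutionalised, 6% died, 12% lost to
follow-up = 33% missing costs) in two flavours: institutionalisation missing
at random (predictive equation) or missing not at random (caregiver time
> 470 h/month, withheld from the imputation models).  Compares a single MI
model against Scenario A (grouped means for lost to follow-up + MI per
reason) and Scenario B (as A, but a fixed institutionalisation cost).
"""

from costmiss import DropoutPatternConfig, MIConfig, analysis_set, generate_cohort
from costmiss.evaluation import MechanismSpec, MethodSpec, run_grid
from costmiss.report import format_summary_table

cohort = analysis_set(generate_cohort(seed=1))
fast = MIConfig(burn_in=100, thin=25)

# fixed cost calibrated near the institutionalised subgroup's true mean
hours = cohort[["hours_adl", "hours_iadl", "hours_supervision"]].sum(axis=1)
inst_mean = float(cohort.loc[hours > 470, "cost_total"].mean())
print(f"true mean of the institutionalised subgroup: EUR {inst_mean:.0f}\n")

mechanisms = [
    MechanismSpec("pattern", pattern_config=DropoutPatternConfig(variant="mar-inst")),
    MechanismSpec("pattern", pattern_config=DropoutPatternConfig(variant="mnar-inst")),
]
methods = [
    MethodSpec("complete_case"),
    MethodSpec("mi", mi_config=fast),
    MethodSpec("combination", scenario="A", mi_config=fast),
    MethodSpec("combination", scenario="B", mi_config=fast, fixed_cost=inst_mean),
]

table = run_grid(cohort, mechanisms, methods, n_iter=30, seed=9)
print(format_summary_table(table))

# Under the MAR flavour a single MI model already does well.  Under the MNAR
# flavour the single MI model underestimates (its covariates exclude the
# unobserved driver), while Scenario B, which substitutes a realistic fixed
# cost for the institutionalised channel, shows the smallest bias — knowing
# WHY data are missing buys more than any one-size-fits-all method.
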