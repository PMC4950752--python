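"""Resampling evaluation of imputation methods.

For one (mechanism x volume x method) cell the experiment bootstrap-resamples
the complete analysis set, imposes the missingness mask on each resample,
applies the estimator, and summarises the iterations with six outcome
measures: mean cost, absolute and relative bias against the complete-sample
("true") mean, sampling standard error (SSE, the SD of the iteration means),
mean standard-error estimate (SEE), their ratio, and the coverage probability
of the nominal 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imputation, missingness
from .imputation import MIConfig

__all__ = [
    "MechanismSpec",
    "MethodSpec",
    "IterationResult",
    "SimulationSummary",
    "run_cell",
    "summarize_cell",
    "run_grid",
]

DEFAULT_VOLUMES = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class MechanismSpec:
    """How to impose missingness on each resample.

    kind: "mcar" | "mar" | "mnar" | "pattern"; volume applies to the first
    three; pattern_config configures the mixed-reason dropout pattern.
    """

    kind: str
    volume: float = 0.0
    pattern_config: missingness.DropoutPatternConfig = field(
        default_factory=missingness.DropoutPatternConfig
    )

    def label(self) -> str:
        if self.kind == "pattern":
            return f"pattern[{self.pattern_config.variant}]"
        return f"{self.kind.upper()}@{self.volume:.0%}"

    def make_mask(self, cohort: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        if self.kind == "mcar":
            return missingness.mcar_mask(cohort, self.volume, seed=rng)
        if self.kind == "mar":
            return missingness.mar_mask(cohort, self.volume)
        if self.kind == "mnar":
            return missingness.mnar_mask(cohort, self.volume)
        if self.kind == "pattern":
            return missingness.dropout_pattern_mask(cohort, self.pattern_config, seed=rng)
        raise ValueError(f"unknown mechanism kind {self.kind!r}")


@dataclass(frozen=True)
class MethodSpec:
    """Which estimator to apply to a masked resample.

    kind: "complete_case" | "grouped_means" | "mi" | "combination".
    For "mi", ``covariates`` names the imputation-model covariates; for
    "combination", ``scenario`` is "A" or "B".
    """

    kind: str
    covariates: tuple[str, ...] = ("mmse", "adcs_adl", "age")
    scenario: str = "A"
    mi_config: MIConfig = field(default_factory=MIConfig)
    fixed_cost: float = imputation.FIXED_INSTITUTIONAL_COST

    def label(self) -> str:
        if self.kind == "combination":
            return f"combination[{self.scenario}]"
        return self.kind

    def estimate(self, cohort: pd.DataFrame, mask: pd.DataFrame,
                 rng: np.random.Generator) -> tuple[float, float, float, float]:
        """Return (mean, SE, ci_low, ci_high) for one masked resample."""
        if self.kind == "complete_case":
            mean, se = imputation.complete_case_estimate(cohort, mask)
            return (mean, se, mean - 1.959964 * se, mean + 1.959964 * se)
        if self.kind == "grouped_means":
            completed = imputation.grouped_means_impute(cohort, mask)
            x = completed["cost_total"].to_numpy(dtype=float)
            mean = float(x.mean())
            se = float(x.std(ddof=1) / np.sqrt(x.size))
            return (mean, se, mean - 1.959964 * se, mean + 1.959964 * se)
        if self.kind == "mi":
            pooled = imputation.mi_mean_estimate(
                cohort, mask, covariates=self.covariates, config=self.mi_config, rng=rng
            )
        elif self.kind == "combination":
            pooled = imputation.combination_impute(
                cohort, mask, scenario=self.scenario, config=self.mi_config,
                rng=rng, fixed_cost=self.fixed_cost,
            )
        else:
            raise ValueError(f"unknown method kind {self.kind!r}")
        lo, hi = pooled.ci()
        return (pooled.estimate, pooled.standard_error, lo, hi)


@dataclass(frozen=True)
class IterationResult:
    iteration: int
    mean_estimate: float
    se_estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.mean_estimate <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class SimulationSummary:
    """The six outcome measures for one simulation cell."""

    mechanism: str
    method: str
    true_mean: float
    mean_cost: float
    absolute_bias: float
    relative_bias_pct: float
    sse: float
    see: float
    see_sse_ratio: float
    coverage_probability: float
    n_iter: int


def run_cell(cohort: pd.DataFrame, mechanism: MechanismSpec, method: MethodSpec,
             n_iter: int = 1000, seed: int | None = None,
             resample: bool = True) -> list[IterationResult]:
    """Run one simulation cell.

    Per iteration: bootstrap-resample the complete analysis set with
    replacement to its own size (skipped when ``resample`` is False), impose
    the mechanism mask on the resample (thresholds re-solved per resample so
    MAR/MNAR volumes stay exact), apply the estimator, and record the
    estimate with its SE and 95% CI.  One master seed spawns an independent
    stream per iteration.
    """
    if method.kind == "combination" and mechanism.kind != "pattern":
        raise ValueError(
            "combination methods need reason channels: use a 'pattern' mechanism"
        )
    n = len(cohort)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_iter)
    results = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sample = cohort.sample(n=n, replace=True, random_state=rng).reset_index(drop=True) \
            if resample else cohort
        if resample:
            # resampling duplicates ids; relabel so masks key uniquely
            sample = sample.assign(patient_id=[f"B{j:05d}" for j in range(n)])
        mask = mechanism.make_mask(sample, rng)
        mean, se, lo, hi = method.estimate(sample, mask, rng)
        results.append(IterationResult(i, mean, se, lo, hi))
    return results


def summarize_cell(iterations: list[IterationResult], true_mean: float,
                   mechanism: str = "", method: str = "") -> SimulationSummary:
    """Aggregate iteration results into the six outcome measures."""
    if len(iterations) < 2:
        raise ValueError("need at least 2 iterations to summarise")
    if true_mean == 0:
        raise ValueError("relative bias is undefined for a zero true mean")
    means = np.array([r.mean_estimate for r in iterations])
    ses = np.array([r.se_estimate for r in iterations])
    cover = np.array([r.ci_low <= true_mean <= r.ci_high for r in iterations])
    mean_cost = float(means.mean())
    sse = float(means.std(ddof=1))
    see = float(ses.mean())
    return SimulationSummary(
        mechanism=mechanism,
        method=method,
        true_mean=float(true_mean),
        mean_cost=mean_cost,
        absolute_bias=mean_cost - true_mean,
        relative_bias_pct=100.0 * (mean_cost - true_mean) / true_mean,
        sse=sse,
        see=see,
        see_sse_ratio=see / sse if sse > 0 else np.inf,
        coverage_probability=float(cover.mean()),
        n_iter=len(iterations),
    )


def true_mean_of(cohort: pd.DataFrame) -> float:
    """The 'true' mean: the complete analysis-set mean of the input cohort."""
    return float(cohort["cost_total"].mean())


def run_grid(cohort: pd.DataFrame, mechanisms: list[MechanismSpec],
             methods: list[MethodSpec], n_iter: int = 1000,
             seed: int | None = None) -> pd.DataFrame:
    """One summary row per (mechanism, method) cell, as a tidy DataFrame."""
    truth = true_mean_of(cohort)
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(mechanisms) * len(methods))
    k = 0
    for mech in mechanisms:
        for meth in methods:
            its = run_cell(cohort, mech, meth, n_iter=n_iter,
                           seed=child_seeds[k])
            k += 1
            s = summarize_cell(its, truth, mechanism=mech.label(), method=meth.label())
            rows.append(s)
    return pd.DataFrame([vars(s) for s in rows])


def default_grid_mechanisms() -> list[MechanismSpec]:
    """The 14 benchmark datasets: 3 mechanisms x 4 volumes + 2 dropout patterns."""
    specs = [MechanismSpec(kind, volume=v)
             for kind in ("mcar", "mar", "mnar") for v in DEFAULT_VOLUMES]
    specs.append(MechanismSpec("pattern", pattern_config=missingness.DropoutPatternConfig(
        variant="mar-inst")))
    specs.append(MechanismSpec("pattern", pattern_config=missingness.DropoutPatternConfig(
        variant="mnar-inst")))
    return specs
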