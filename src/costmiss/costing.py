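"""Informal-caregiver time valuation and total societal cost.

Base case: caregiver time on basic plus instrumental ADL (supervision
excluded), valued at an opportunity cost that differs by the caregiver's
working status; the informal-care cost of a record is the higher of the care
time cost and the missed-work cost, with the same unit cost applied to both.
Three alternative schemes are supported: including supervision time, a
replacement-cost valuation (single unit cost regardless of working status),
and costing the time of working caregivers only.

Default unit costs are placeholders for demonstration, not study-derived
country wages: set them explicitly for any substantive analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH

__all__ = ["CostingOptions", "informal_care_cost", "total_societal_cost",
           "costing_variants", "cohort_cost_summary"]

FIXED_COMPONENTS = ("cost_patient_healthcare", "cost_patient_social",
                    "cost_caregiver_healthcare")


@dataclass(frozen=True)
class CostingOptions:
    """Valuation switches for caregiver time (unit costs in EUR/hour)."""

    include_supervision: bool = False
    valuation: str = "opportunity"          # "opportunity" | "replacement"
    working_only: bool = False
    unit_cost_working: float = 20.0
    unit_cost_nonworking: float = 10.0
    unit_cost_replacement: float = 15.0
    hour_cap: float = 24.0                  # hours/day cap on summed care time

    def validate(self) -> None:
        if min(self.unit_cost_working, self.unit_cost_nonworking,
               self.unit_cost_replacement) < 0:
            raise ValueError("unit costs must be non-negative")
        if not 0 < self.hour_cap <= 24:
            raise ValueError("hour_cap must be in (0, 24]")
        if self.valuation not in ("opportunity", "replacement"):
            raise ValueError("valuation must be 'opportunity' or 'replacement'")


BASE_CASE = CostingOptions()


def _unit_cost(working: np.ndarray, options: CostingOptions) -> np.ndarray:
    if options.valuation == "replacement":
        return np.full(working.shape, options.unit_cost_replacement)
    return np.where(working, options.unit_cost_working, options.unit_cost_nonworking)


def informal_care_cost(record, options: CostingOptions = BASE_CASE):
    """Monthly informal-care cost of a record (or of every cohort row).

    Care hours H = ADL + IADL (+ supervision if included), capped at
    hour_cap x days/month; the result is max(H x u, missed-work hours x u)
    with u the valuation- and working-status-dependent unit cost.  Under
    ``working_only`` the time of non-working caregivers is not costed.
    """
    options.validate()
    df = record if isinstance(record, pd.DataFrame) else pd.DataFrame([record])
    hours = df["hours_adl"].to_numpy(dtype=float) + df["hours_iadl"].to_numpy(dtype=float)
    if options.include_supervision:
        hours = hours + df["hours_supervision"].to_numpy(dtype=float)
    hours = np.minimum(hours, options.hour_cap * DAYS_PER_MONTH)
    working = df["caregiver_working"].to_numpy(dtype=bool)
    u = _unit_cost(working, options)
    cost = np.maximum(hours * u, df["hours_missed_work"].to_numpy(dtype=float) * u)
    if options.working_only:
        cost = np.where(working, cost, 0.0)
    return cost if isinstance(record, pd.DataFrame) else float(cost[0])


def total_societal_cost(record, options: CostingOptions = BASE_CASE):
    """Patient healthcare + patient social + caregiver healthcare + informal care."""
    df = record if isinstance(record, pd.DataFrame) else pd.DataFrame([record])
    fixed = sum(df[c].to_numpy(dtype=float) for c in FIXED_COMPONENTS)
    total = fixed + informal_care_cost(df, options)
    return total if isinstance(record, pd.DataFrame) else float(total[0])


def costing_variants(base: CostingOptions = BASE_CASE) -> dict[str, CostingOptions]:
    """The base case and the three alternative valuation schemes."""
    return {
        "base_case": base,
        "with_supervision": replace(base, include_supervision=True),
        "replacement_cost": replace(base, valuation="replacement",
                                    include_supervision=True),
        "working_caregivers_only": replace(base, working_only=True),
    }


def cohort_cost_summary(cohort: pd.DataFrame,
                        base: CostingOptions = BASE_CASE) -> pd.DataFrame:
    """Mean total societal cost under each valuation variant, with % change.

    The replacement-cost variant includes supervision time (single unit cost
    for all caregivers, supervision included), matching how that alternative
    is conventionally reported.
    """
    rows = []
    base_mean = None
    for name, opts in costing_variants(base).items():
        total = total_societal_cost(cohort, opts)
        mean = float(np.nanmean(total))
        if name == "base_case":
            base_mean = mean
        rows.append({
            "variant": name,
            "mean_cost": mean,
            "pct_change_vs_base": 100.0 * (mean - base_mean) / base_mean,
        })
    return pd.DataFrame(rows)
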