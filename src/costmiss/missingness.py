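"""Missing-data mechanisms for total monthly cost.

Each mask returns one assignment row per cohort patient: an ``is_missing``
flag and a reason channel.  MCAR selects uniformly at random; MAR deletes the
patients with the worst combined cognition/function score; MNAR deletes the
most expensive patients.  The mixed-reason dropout pattern emulates the
discontinuation structure seen over long follow-up of community-dwelling
dementia cohorts: institutionalisation (15%), death (6%) and loss to
follow-up (12%), for 33% missing cost data overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REASONS",
    "DropoutPatternConfig",
    "mcar_mask",
    "mar_mask",
    "mnar_mask",
    "dropout_pattern_mask",
    "apply_mask",
]

REASONS = ("observed", "generic", "institutionalised", "died", "lost_to_followup")


class VolumeError(ValueError):
    """Raised when a requested missing-data volume is not a valid fraction."""


def _check_volume(volume: float) -> None:
    if not 0 <= volume < 1:
        raise VolumeError(f"missing-data volume must be in [0, 1), got {volume}")


def _empty_mask(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "is_missing": np.zeros(len(cohort), dtype=bool),
            "reason": np.full(len(cohort), "observed", dtype=object),
        }
    )


def _finalize(mask: pd.DataFrame, miss_idx: np.ndarray, reason: str) -> pd.DataFrame:
    mask.loc[miss_idx, "is_missing"] = True
    mask.loc[miss_idx, "reason"] = reason
    return mask


def mcar_mask(cohort: pd.DataFrame, volume: float, seed=None) -> pd.DataFrame:
    """Missing completely at random: k = round(volume*n) uniform draws."""
    _check_volume(volume)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    k = int(round(volume * n))
    mask = _empty_mask(cohort)
    idx = rng.choice(n, size=k, replace=False)
    return _finalize(mask, idx, "generic")


def _severity_score(cohort: pd.DataFrame) -> np.ndarray:
    """z(MMSE) + z(ADCS-ADL): low = worst cognition and function."""
    out = np.zeros(len(cohort))
    for col in ("mmse", "adcs_adl"):
        x = cohort[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        out += (x - x.mean()) / sd if sd > 0 else 0.0
    return out


def _bottom_k(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest values; ties broken by stable input order."""
    return np.argsort(values, kind="stable")[:k]


def mar_mask(cohort: pd.DataFrame, volume: float) -> pd.DataFrame:
    """Missing at random: delete the worst-scoring fraction on z(MMSE)+z(ADL).

    Deterministic given the cohort — the score threshold is implicitly set to
    achieve the requested volume exactly.
    """
    _check_volume(volume)
    n = len(cohort)
    k = int(round(volume * n))
    score = _severity_score(cohort)
    return _finalize(_empty_mask(cohort), _bottom_k(score, k), "generic")


def mnar_mask(cohort: pd.DataFrame, volume: float) -> pd.DataFrame:
    """Missing not at random: delete the top-cost fraction of the cohort.

    Every deleted cost exceeds every observed cost (ties broken by stable
    patient order and logged).
    """
    _check_volume(volume)
    n = len(cohort)
    k = int(round(volume * n))
    cost = cohort["cost_total"].to_numpy(dtype=float)
    order = _bottom_k(-cost, n)
    if 0 < k < n and cost[order[k - 1]] == cost[order[k]]:
        logger.warning("tied total costs at the MNAR threshold; ties broken by patient order")
    return _finalize(_empty_mask(cohort), order[:k], "generic")


@dataclass(frozen=True)
class DropoutPatternConfig:
    """Mixed-reason dropout pattern over 18-month-style follow-up.

    ``variant`` selects how institutionalisation is generated:

    - ``"mar-inst"``: a predictive (logistic-score) equation on observed
      MMSE, ADCS-ADL and caregiver time — missingness at random.
    - ``"mnar-inst"``: the deterministic rule caregiver time > threshold
      (470 h/month by default); caregiver time is then withheld from the
      imputation models, making the channel missing not at random.
    """

    rate_institutionalised: float = 0.15
    rate_died: float = 0.06
    rate_ltfu: float = 0.12
    variant: str = "mar-inst"
    caregiver_time_threshold: float = 470.0
    # Logistic-score coefficients per unit of each covariate.  The intercept
    # is irrelevant under exact-count selection and therefore omitted.
    inst_coefs: dict[str, float] = field(
        default_factory=lambda: {"mmse": -0.08, "adcs_adl": -0.03, "caregiver_hours": 0.002}
    )
    death_coefs: dict[str, float] = field(
        default_factory=lambda: {"mmse": -0.05, "adcs_adl": -0.02, "age": 0.05}
    )

    def validate(self) -> None:
        rates = (self.rate_institutionalised, self.rate_died, self.rate_ltfu)
        if any(r < 0 for r in rates):
            raise VolumeError("dropout rates must be non-negative")
        if sum(rates) > 1:
            raise VolumeError("dropout rates must sum to at most 1")
        if self.variant not in ("mar-inst", "mnar-inst"):
            raise ValueError(f"unknown variant {self.variant!r}")


def _weighted_top_k(logits: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample exactly k items without replacement, odds tilted by the logits.

    Gumbel-top-k on the logistic scores: the realised channel count equals its
    target exactly while higher-risk patients remain more likely to be chosen.
    """
    if k <= 0:
        return np.empty(0, dtype=int)
    keys = logits + rng.gumbel(size=logits.size)
    return np.argsort(-keys, kind="stable")[:k]


def dropout_pattern_mask(
    cohort: pd.DataFrame, config: DropoutPatternConfig | None = None, seed=None
) -> pd.DataFrame:
    """Assign reasons in the order institutionalised -> died -> lost to follow-up.

    Channel counts are round(rate x n) of the full cohort, so the overall
    missing fraction equals the sum of the configured rates up to rounding.
    Under ``"mnar-inst"`` the institutionalised set is instead everyone whose
    total caregiver time strictly exceeds the threshold; a calibration warning
    is logged if that fraction deviates more than 20% (relative) from the
    configured rate.
    """
    config = config or DropoutPatternConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    mask = _empty_mask(cohort)

    hours = (
        cohort[["hours_adl", "hours_iadl", "hours_supervision"]].sum(axis=1).to_numpy(dtype=float)
    )

    if config.variant == "mnar-inst":
        inst_idx = np.flatnonzero(hours > config.caregiver_time_threshold)
        frac = len(inst_idx) / n if n else 0.0
        target = config.rate_institutionalised
        if target > 0 and abs(frac - target) / target > 0.20:
            logger.warning(
                "caregiver-time threshold rule institutionalised %.1f%% of the cohort "
                "(target %.1f%%): calibration deviates by more than 20%% relative",
                100 * frac, 100 * target,
            )
    else:
        logits = np.zeros(n)
        for var, coef in config.inst_coefs.items():
            x = hours if var == "caregiver_hours" else cohort[var].to_numpy(dtype=float)
            logits += coef * x
        k_inst = int(round(config.rate_institutionalised * n))
        inst_idx = _weighted_top_k(logits, k_inst, rng)
    _finalize(mask, inst_idx, "institutionalised")

    remaining = np.flatnonzero(~mask["is_missing"].to_numpy())
    death_logits = np.zeros(len(remaining))
    for var, coef in config.death_coefs.items():
        death_logits += coef * cohort[var].to_numpy(dtype=float)[remaining]
    k_died = min(int(round(config.rate_died * n)), len(remaining))
    died_idx = remaining[_weighted_top_k(death_logits, k_died, rng)]
    _finalize(mask, died_idx, "died")

    remaining = np.flatnonzero(~mask["is_missing"].to_numpy())
    k_ltfu = min(int(round(config.rate_ltfu * n)), len(remaining))
    ltfu_idx = rng.choice(remaining, size=k_ltfu, replace=False)
    _finalize(mask, ltfu_idx, "lost_to_followup")
    return mask


def apply_mask(cohort: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort with masked total costs set to NaN."""
    out = cohort.copy()
    missing_ids = set(mask.loc[mask["is_missing"], "patient_id"])
    out.loc[out["patient_id"].isin(missing_ids), "cost_total"] = np.nan
    return out
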