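import numpy as np
import pandas as pd
import pytest

from costmiss import GenerationParams, analysis_set, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default-calibrated cohort (n=1497), generated once per session."""
    return generate_cohort(GenerationParams(seed=1))


@pytest.fixture(scope="session")
def cohort_analysis(default_cohort) -> pd.DataFrame:
    """The cost-complete analysis set of the default cohort (n=1488)."""
    return analysis_set(default_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160718)


@pytest.fixture(scope="session")
def tiny_cohort() -> pd.DataFrame:
    """Hand-built six-patient cohort for arithmetic-level checks."""
    return pd.DataFrame(
        {
            "patient_id": [f"T{i}" for i in range(6)],
            "age": [70.0, 75, 80, 85, 72, 78],
            "sex": ["female"] * 3 + ["male"] * 3,
            "mmse": [24, 22, 18, 16, 10, 8],
            "adcs_adl": [60, 55, 40, 35, 20, 15],
            "hours_adl": [10.0, 20, 40, 60, 100, 120],
            "hours_iadl": [10.0, 15, 30, 40, 60, 80],
            "hours_supervision": [0.0, 10, 20, 50, 100, 200],
            "hours_missed_work": [5.0, 0, 0, 30, 0, 0],
            "caregiver_working": [True, False, False, True, False, True],
            "cost_patient_healthcare": [300.0, 400, 500, 600, 700, 800],
            "cost_patient_social": [100.0, 150, 200, 250, 300, 350],
            "cost_caregiver_healthcare": [50.0, 60, 70, 80, 90, 100],
            "cost_informal_care": [200.0, 350, 700, 1000, 1600, 2000],
            "cost_total": [650.0, 960, 1470, 1930, 2690, 3250],
            "baseline_complete": [True] * 6,
        }
    )
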