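import numpy as np
import pandas as pd
import pytest

from sarco_cutpoint.cohort_ops import Cohort
from sarco_cutpoint.synthetic_cohort import (
    SimulationParams,
    StepHazardSpec,
    generate_cohort,
)


def make_cohort(df: pd.DataFrame, label: str = "full") -> Cohort:
    """Fill schema defaults so tests can specify only the columns they care about."""
    defaults = {
        "sex": "M",
        "age": 55.0,
        "dm": 0,
        "cvd": 0,
        "albumin": 35.0,
        "height": 165.0,
        "weight": 62.0,
        "hgs": 22.0,
        "lmi": 15.6,
        "dialysis_duration": 2.0,
        "time": 36.0,
        "cause": "admin_censor",
    }
    df = df.copy()
    if "id" not in df.columns:
        df["id"] = [f"P{i}" for i in range(len(df))]
    for col, value in defaults.items():
        if col not in df.columns:
            df[col] = value
    return Cohort(df, label)


@pytest.fixture(scope="session")
def proportional_cohort() -> Cohort:
    """A moderately sized covariate-driven cohort, shared across tests."""
    return generate_cohort(SimulationParams(n=4000, seed=11))


@pytest.fixture(scope="session")
def step_cohort() -> Cohort:
    """Known-threshold cohort: HR 2 below 24.5 kg (M) / 14.0 kg (F) of HGS."""
    return generate_cohort(
        SimulationParams(n=3000, seed=23), StepHazardSpec(hr_below=2.0)
    )
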