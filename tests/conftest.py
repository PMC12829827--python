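import numpy as np
import pandas as pd
import pytest

from countreg.distributions import FamilySpec
from countreg.synth import RegressionScenario, generate_monthly_design

SMALL_LAW = {
    "x_share": {"kind": "proportion", "mean": 0.6, "concentration": 16.0},
    "x_score": {"kind": "continuous", "mean": 2.0, "sd": 0.5},
    "x_lab": {"kind": "continuous", "mean": 8.0, "sd": 1.0},
}


def small_scenario(family=FamilySpec("negbin", 0.5), n_months=80, seed=0,
                   beta=(1.0, 1.2, 0.5, 0.0)):
    """Compact 3-covariate scenario used across the unit tests."""
    return RegressionScenario(
        n_months=n_months, beta=tuple(beta), family=family,
        covariate_law=SMALL_LAW, seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return generate_monthly_design(small_scenario())


@pytest.fixture
def patient_table():
    """Tiny hand-built patient table with gaps, for the cleaning tests."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "diagnosis_date": [
                "2020-01-15", "2020-01-20", "2020-02-01",
                "2020-02-10", "2020-04-05", "2020-04-06",
            ],
            "age": [40.0, np.nan, 60.0, 55.0, 15.0, 45.0],
            "smoking": ["Yes", "Yes", np.nan, "No", "Yes", "Yes"],
            "marital_status": ["Married", "Not Married", "Married",
                               "Married", np.nan, "Married"],
            "bmi": [31.0, 27.0, 24.0, np.nan, 33.0, 29.0],
        }
    )
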