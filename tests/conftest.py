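import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from depmed import GeneratorConfig, generate_cohort, validate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("depmed").setLevel(logging.ERROR)


def small_cohort_df(n=6):
    """A tiny hand-written cohort covering every column the models use."""
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "site": ["S01", "S02"] * (n // 2),
        "time_days": np.linspace(200.0, 1800.0, n),
        "event": [1, 0] * (n // 2),
        "stage": ["localized", "regional", "distant"] * (n // 3),
        "debulk": ["optimal", "suboptimal"] * (n // 2),
        "histology": ["serous"] * n,
        "adjuvant": [1] * n,
        "neoadjuvant": [0] * n,
        "age_dx": np.linspace(45.0, 70.0, n),
        "bmi": np.linspace(24.0, 38.0, n),
        "income_cat": ["<10k", "10-25k", "25-50k"] * (n // 3),
        "smoking": ["never", "ever"] * (n // 2),
        "paga": ["yes", "no"] * (n // 2),
        "tract_id": [f"T{i % 3}" for i in range(n)],
        "URB": np.linspace(-1.5, 0.8, n),
        "ADI": np.linspace(80.0, 140.0, n),
    })


@pytest.fixture
def cohort_df():
    return small_cohort_df()


@pytest.fixture
def cohort(cohort_df):
    return validate_cohort(cohort_df)


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=20231004), truth_draws=5_000)
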