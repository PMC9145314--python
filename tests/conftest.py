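import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from goldpath.fitting import DoseResponseDataset
from goldpath.models import ModelSpec
from goldpath.synth import DoseResponseTruth, gen_dose_response


@pytest.fixture
def e2_noisy() -> tuple[DoseResponseTruth, DoseResponseDataset]:
    truth = DoseResponseTruth(
        ModelSpec("exponential", 2, a=100.0, b=-0.03), log_sd=0.05, seed=11
    )
    return truth, gen_dose_response(truth)


@pytest.fixture
def e3_noisy() -> tuple[DoseResponseTruth, DoseResponseDataset]:
    truth = DoseResponseTruth(
        ModelSpec("exponential", 3, a=100.0, b=-0.002, d=1.5), log_sd=0.05, seed=5
    )
    return truth, gen_dose_response(truth)


@pytest.fixture
def wst_plate() -> pd.DataFrame:
    """Minimal WST-1 plate: one treatment, duplicate wells per role."""
    rows = [
        ("cells_treatment", "X", 0.8, 0.0), ("cells_treatment", "X", 0.8, 0.0),
        ("medium_treatment", "X", 0.2, 0.0), ("medium_treatment", "X", 0.2, 0.0),
        ("cells_control", "", 1.2, 0.0), ("cells_control", "", 1.2, 0.0),
        ("medium_control", "", 0.2, 0.0), ("medium_control", "", 0.2, 0.0),
    ]
    return pd.DataFrame(rows, columns=["role", "treatment", "A440", "A620"])


@pytest.fixture
def feature_table() -> pd.DataFrame:
    """10 features, 3 of which each fail exactly one reliability criterion."""
    rng = np.random.default_rng(0)
    n = 10
    table = pd.DataFrame({
        "feature_id": [f"P{i}" for i in range(n)],
        "symbol": [f"G{i % 5}" for i in range(n)],
        "above_noise": [True] * n,
        "below_saturation": [True] * n,
        "population_outlier": [False] * n,
        "uniform_spot": [True] * n,
        "is_control": [False] * n,
        "s1": rng.uniform(50, 5000, n),
        "s2": rng.uniform(50, 5000, n),
        "s3": rng.uniform(50, 5000, n),
    })
    table.loc[1, "above_noise"] = False
    table.loc[4, "population_outlier"] = True
    table.loc[7, "is_control"] = True
    return table
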