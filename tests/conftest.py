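import numpy as np
import pandas as pd
import pytest

from ssbreform import ModelParams, PopulationConfig, generate_population


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def pop_small() -> pd.DataFrame:
    """400-record seeded population for simulation-heavy tests."""
    cfg = PopulationConfig(n_records=400, n_strata=10, seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def pop_default() -> pd.DataFrame:
    """Full-size seeded population with the default configuration."""
    return generate_population(PopulationConfig(), seed=1)


@pytest.fixture()
def reference_adult() -> pd.Series:
    return pd.Series(
        {
            "id": 1,
            "sex": "male",
            "age": 35.0,
            "height": 1.70,
            "weight": 70.0,
            "ses": "middle",
            "tei_init": 2000.0,
            "sugar_total": 250.0,
            "sugar_ssb": 100.0,
            "sugar_other": 150.0,
            "survey_weight": 1.0,
            "stratum": 1,
            "psu": 1,
        }
    )


def weighted_mean_oracle(values, weights) -> float:
    """Brute-force per-record weighted mean used as an independent check."""
    num = 0.0
    den = 0.0
    for v, w in zip(values, weights):
        num += v * w
        den += w
    return num / den
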