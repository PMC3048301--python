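from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rvpsim import default_calibration, generate_population, load_score_coefficients
from rvpsim.score import score_population


@pytest.fixture(scope="session")
def coeffs():
    return load_score_coefficients()


@pytest.fixture(scope="session")
def default_config():
    return default_calibration()


@pytest.fixture(scope="session")
def small_config(default_config):
    """Shipped calibration scaled down to ~2400 individuals for fast tests."""
    return replace(default_config, sample_fraction=0.0001, seed=202)


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_scored(small_population, coeffs):
    return score_population(small_population, coeffs)


def make_individuals(rows):
    """Build a minimal population frame from (sex, age, sbp, dbp, tchol,
    smoker, diabetic) tuples."""
    df = pd.DataFrame(
        rows, columns=["sex", "age", "sbp", "dbp", "tchol", "smoker", "diabetic"]
    )
    df.insert(0, "id", np.arange(len(df)))
    df.insert(2, "age_class", [
        "35-44" if a < 45 else "45-54" if a < 55 else "55-64" for a in df["age"]
    ])
    df["smoker"] = df["smoker"].astype(bool)
    df["diabetic"] = df["diabetic"].astype(bool)
    return df
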