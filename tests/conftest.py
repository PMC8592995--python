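"""Shared fixtures: the printed four-protein worked example and small studies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from glycopattern.patterns import DoseDesign
from glycopattern.synthetic import SimulationConfig, simulate_dose_response

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DOSE_COLUMNS = ["0nM", "0.1nM", "1.0nM", "10nM"]

#: Published spike-normalized total protein abundances for the four proteins
#: verified by western blot (vehicle, 0.1, 1.0, 10 nM R1881).
TABLE1 = {
    "PRKDC": (3.72e7, 2.71e7, 3.29e7, 2.44e7),
    "GAPDH": (9.66e7, 9.03e7, 2.48e7, 3.06e7),
    "ATP1B1": (8.18e6, 4.97e6, 1.40e7, 2.86e5),
    "CLTC": (2.99e8, 1.93e8, 1.95e8, 1.43e8),
}


@pytest.fixture()
def table1() -> pd.DataFrame:
    return pd.DataFrame.from_dict(TABLE1, orient="index", columns=DOSE_COLUMNS)


@pytest.fixture()
def dose_design() -> DoseDesign:
    return DoseDesign(baseline_sample="0nM",
                      treated_samples=("0.1nM", "1.0nM", "10nM"))


@pytest.fixture()
def small_study():
    config = SimulationConfig(n_proteins=120, seed=7,
                              missing_rate_per_condition=(0.1, 0.1, 0.1, 0.1))
    return simulate_dose_response(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
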