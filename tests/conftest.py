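import warnings

import numpy as np
import pandas as pd
import pytest

import costutility as cu

warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")


def small_config(seed: int = 11, n_per_arm: int = 60, practices: int = 8) -> cu.TrialConfig:
    cfg = cu.TrialConfig.default(seed=seed)
    cfg.n_patients = {"CSC": n_per_arm, "TAU": n_per_arm}
    cfg.n_practices_per_arm = practices
    return cfg


@pytest.fixture(scope="session")
def unit_table() -> cu.UnitCostTable:
    return cu.UnitCostTable.default()


@pytest.fixture(scope="session")
def small_trial() -> cu.SyntheticTrial:
    """Small masked trial shared across tests (60/arm, 8 practices/arm)."""
    return cu.generate_trial(small_config())


@pytest.fixture(scope="session")
def complete_trial() -> cu.SyntheticTrial:
    """Trial without missingness for oracle-style checks."""
    cfg = small_config(seed=13)
    cfg.missingness = cu.MissingnessConfig.none()
    return cu.generate_trial(cfg)


@pytest.fixture(scope="session")
def valued_complete(complete_trial, unit_table) -> pd.DataFrame:
    costs, rejects = cu.value_utilization(complete_trial.complete, unit_table)
    assert rejects.empty
    return pd.concat([complete_trial.complete, costs], axis=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
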