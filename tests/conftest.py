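import numpy as np
import pytest
from hypothesis import settings

from rootkin.config import (
    DiameterTaper,
    LogisticTruth,
    ScenarioConfig,
    builtin_scenario,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return np.round(np.arange(0.0, 12.0 + 1e-9, 0.1), 10)


@pytest.fixture()
def ww():
    return builtin_scenario("WW", seed=1)


@pytest.fixture()
def wd():
    return builtin_scenario("WD", seed=1)


@pytest.fixture()
def tiny_scenario():
    """Minimal hand-parameterised scenario for unit tests."""
    return ScenarioConfig(
        name="WW",
        elong_rate_cm_per_day=3.08,
        final_cell_len_um=156.9,
        logistic_truth=LogisticTruth(a1=0.05, a2=3.08 * 10 / 24, x0=3.24228, p=2.90058),
        plateau_start_mm=10.0,
        diameter_taper=DiameterTaper(d_tip_mm=0.9, d_mature_mm=1.1, decay_mm=4.0),
        n_plants=9,
        length_sd_cm=1.0,
        met_effects={"proline": {"R1": 18.6}, "saccharopine": {"R3": 67.5}},
        met_cv=0.10,
        met_n_reps=3,
        seed=7,
    )
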