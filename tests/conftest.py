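import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import paycharge as pc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """A small but complete simulated world with stay-level records."""
    cfg = pc.SimConfig(
        n_states=4, hospitals_per_state=25, seed=42,
        stay_count_mean={p: 80.0 for p in pc.PAYERS},
    )
    return pc.simulate(cfg)


@pytest.fixture(scope="session")
def small_obs(small_world):
    obs, _ = pc.build_observations(
        small_world.stays, small_world.hospitals, small_world.states)
    return obs


@pytest.fixture()
def toy_stays():
    """Six stays at one hospital, hand-enumerable."""
    return pd.DataFrame({
        "hospital_id": ["H1"] * 6,
        "state_id": ["S1"] * 6,
        "payer": ["medicare"] * 6,
        "female": [1, 1, 0, 0, 1, 0],
        "age_band": ["56_plus", "56_plus", "46_55", "0_17", "56_plus", "18_35"],
        "race": ["white", "white", "black", "hispanic", "other", "white"],
        "died": [1, 0, 0, 0, 1, 0],
        "severity": [2, 2, 3, 1, 4, 0],
        "los_days": [5.0, 3.0, 10.0, 2.0, 7.0, 3.0],
        "drg_weight": [1.2, 0.8, 2.0, 0.6, 1.5, 0.9],
        "charge": [100.0, 200.0, 300.0, 150.0, 250.0, 100.0],
        "payment": [50.0, 40.0, 210.0, 30.0, 100.0, 20.0],
    })
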