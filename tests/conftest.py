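import copy

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grazekit import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> sd.SimulationConfig:
    return sd.default_config()


@pytest.fixture()
def small_cfg(default_cfg) -> sd.SimulationConfig:
    """Shrunk study: same structure, far fewer records (fast tests)."""
    raw = copy.deepcopy(default_cfg.raw)
    raw["transects"]["months"] = {"wet": ["Jan"], "dry": ["Jun"]}
    raw["transects"]["transects_per_month"] = 1
    raw["transects"]["points_per_transect"] = 8
    raw["trial"]["n_grazed_swards_per_camp"] = 8
    raw["trial"]["clipping"]["n_replicates_per_schedule"] = 5
    for herb in ("oribi", "cattle"):
        n_obs = raw["foraging"][herb]["n_observations"]
        for season in n_obs:
            n_obs[season] = {camp: 4 for camp in n_obs[season]}
    return sd.SimulationConfig(raw)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
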