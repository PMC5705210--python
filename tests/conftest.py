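import numpy as np
import pytest

from zfsleep import LightSchedule, SimConfig
from zfsleep.config import GroupSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Two small groups with distinct day/night sleep pressure."""
    return SimConfig(
        n_larvae=4,
        groups=[
            GroupSpec(label="wt"),
            GroupSpec(
                label="mut",
                activity_multiplier=0.5,
                p_wake_to_sleep={"day": 0.05, "night": 0.12},
                p_sleep_to_wake={"day": 0.20, "night": 0.08},
            ),
        ],
        seed=7,
    )


@pytest.fixture
def schedule():
    return LightSchedule(lights_on=9.0, lights_off=23.0, n_days=2)
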