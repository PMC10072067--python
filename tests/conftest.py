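import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flychrono.dam_io import ActivityRecording, LightSchedule

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

LIGHTS_ON = dt.time(8, 0)
START = dt.datetime(2024, 1, 1, 8, 0)  # recording starts at lights-on


@pytest.fixture
def schedule() -> LightSchedule:
    return LightSchedule(lights_on_clock=LIGHTS_ON)


@pytest.fixture
def make_recording(schedule):
    """Factory for recordings starting at lights-on with 5-min bins."""

    def _make(counts, genotype="wt", masked=None, start=START, sched=schedule):
        return ActivityRecording(
            fly_id="M1#01",
            genotype=genotype,
            start_time=start,
            counts=np.asarray(counts),
            schedule=sched,
            masked=masked,
        )

    return _make
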