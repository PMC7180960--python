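import datetime as dt

import numpy as np
import pytest

from habitspectrum import ActivityEvent, ActivityRegistry, HabitSequence


@pytest.fixture
def tv_sleep_registry() -> ActivityRegistry:
    """Two-activity registry: watching TV = 1, sleeping = 2."""
    return ActivityRegistry((("watching_tv", 1), ("sleeping", 2)))


@pytest.fixture
def sleep_then_tv(tv_sleep_registry) -> HabitSequence:
    """Slept 10 min, then watched TV 60 min."""
    return HabitSequence(
        subject="u1",
        window_label="session",
        ids=(tv_sleep_registry.id_of("sleeping"), tv_sleep_registry.id_of("watching_tv")),
        durations=(10.0, 60.0),
    )


@pytest.fixture
def breakfast_events() -> list[ActivityEvent]:
    """Eating breakfast 30 min then watching TV 60 min, one subject, one day."""
    d = dt.date(2020, 1, 6)
    return [
        ActivityEvent(subject="u1", date=d, order_index=0, activity_id=3, duration=30.0),
        ActivityEvent(subject="u1", date=d, order_index=1, activity_id=1, duration=60.0),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
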