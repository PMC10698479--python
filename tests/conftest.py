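import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from focalscan.obsdata import (
    Behaviour,
    FocalSession,
    GroupRoster,
    Individual,
    Method,
    ObservationEvent,
    ScanSession,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


T0 = 0.0
HOUR = 3600.0
DAY = 86400.0


def make_event(actor, recipient, t=100.0, behaviour="grooming", method="FAS", session="s1"):
    return ObservationEvent(
        timestamp=t, behaviour=Behaviour(behaviour), actor_id=actor,
        recipient_id=recipient, method=Method(method), session_id=session,
    )


@pytest.fixture
def toy_roster():
    """Four individuals, all resident from t=0 with no departures."""
    return GroupRoster(
        group_id="G",
        members=[
            Individual(id=i, sex="F", group_id="G", entry_time=T0) for i in "abcd"
        ],
    )


@pytest.fixture
def toy_focal_sessions():
    """Six consecutive 10-minute follows starting at t=0."""
    return [
        FocalSession(session_id=f"f{k}", focal_id="a", start=k * 600.0, duration=600.0)
        for k in range(6)
    ]


@pytest.fixture
def toy_scan_sessions():
    """Twelve 10-minute scans, one per hour."""
    return [
        ScanSession(session_id=f"s{k}", start=k * HOUR, duration=600.0,
                    visible_ids=frozenset("abcd"))
        for k in range(12)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
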