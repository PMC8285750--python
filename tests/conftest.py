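import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from birdsearch.difficulty import default_table
from birdsearch.neglect import default_sheet
from birdsearch.simulator import AgentProfile, SessionRecord, TargetEvent, RoundRecord, TaskConfig


@pytest.fixture
def table():
    return default_table()


@pytest.fixture
def sheet():
    return default_sheet()


def make_session(search_times_by_hemispace, misses_left=0, misses_right=0,
                 level=1, lifetime=15.0):
    """Hand-built resolved session: search_times_by_hemispace is a dict
    {'left': [...], 'right': [...]} of found search times."""
    events = []
    for side, times in search_times_by_hemispace.items():
        sign = -1.0 if side == "left" else 1.0
        for st in times:
            events.append(TargetEvent(
                round_index=0, level=level, spawn_time=0.0,
                azimuth=sign * 30.0, elevation=0.0, direction=1,
                speed=2.0, lifetime=lifetime, found=True, search_time=st))
    for side, n in (("left", misses_left), ("right", misses_right)):
        sign = -1.0 if side == "left" else 1.0
        for _ in range(n):
            events.append(TargetEvent(
                round_index=0, level=level, spawn_time=0.0,
                azimuth=sign * 30.0, elevation=0.0, direction=1,
                speed=2.0, lifetime=lifetime, found=False, search_time=None))
    return SessionRecord(
        participant_id="t", cohort="test", agent=AgentProfile(),
        config=TaskConfig(), rounds=[RoundRecord(level=level, events=events)])
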