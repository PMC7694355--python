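from datetime import datetime, timedelta

import pytest

from tempolink.records import EDVisit, HospitalEpisode


def make_visit(pid="P1", vid="V1", arrival="2010-03-01 10:00", los_min=270,
               status="ward_this_hospital", **kw) -> EDVisit:
    a = datetime.strptime(arrival, "%Y-%m-%d %H:%M")
    return EDVisit(
        participant_id=pid, visit_id=vid, arrival_dt=a,
        departure_dt=a + timedelta(minutes=los_min),
        departure_status=status, **kw)


def make_episode(pid="P1", eid="E1", admission="2010-03-01 12:00", los_min=2880,
                 atype="emergency_this_hospital", mode="home", **kw) -> HospitalEpisode:
    h = datetime.strptime(admission, "%Y-%m-%d %H:%M")
    return HospitalEpisode(
        participant_id=pid, episode_id=eid, admission_dt=h,
        separation_dt=h + timedelta(minutes=los_min),
        admission_type=atype, separation_mode=mode, **kw)


@pytest.fixture
def visit_factory():
    return make_visit


@pytest.fixture
def episode_factory():
    return make_episode
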