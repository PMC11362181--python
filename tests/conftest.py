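from datetime import date, datetime

import pytest

from dyadprox.types import BeaconAssignment, Participant, Roster, StudyConfig

START = date(2019, 3, 4)  # a Monday
END = date(2019, 3, 17)  # 14-day window: 10 weekdays + 4 weekend days


def make_participant(
    person_id,
    family_id,
    role,
    major,
    minor,
    start=START,
    end=END,
    assignments=None,
):
    return Participant(
        person_id=person_id,
        family_id=family_id,
        role=role,
        device_ids=frozenset({f"dev-{person_id}"}),
        beacon_assignments=assignments
        or (BeaconAssignment(major, minor, start - date.resolution * 60, end + date.resolution * 60),),
        participation_start=start,
        participation_end=end,
    )


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def roster():
    """Two families: F01 with both parents, F02 mother-only."""
    return Roster(
        [
            make_participant("F01-adolescent", "F01", "adolescent", 1, 1),
            make_participant("F01-mother", "F01", "mother", 1, 2),
            make_participant("F01-father", "F01", "father", 1, 3),
            make_participant("F02-adolescent", "F02", "adolescent", 2, 1),
            make_participant("F02-mother", "F02", "mother", 2, 2),
        ]
    )


def ts(day: int, hour: int, minute: int = 0, second: int = 0) -> datetime:
    """Timestamp on the day-th study day (1-based from the Monday start)."""
    d = date(START.year, START.month, START.day)
    return datetime(d.year, d.month, d.day + day - 1, hour, minute, second)
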