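"""Core domain types for BLE-beacon dyadic proximity tracking.

A study consists of families wearing iBeacon cards (study UUID, family-level
``major``, member-level ``minor``) while a phone app scans for nearby beacons
roughly every five minutes.  These types model one beacon detection, the study
roster (who wore which beacon when, on which devices, over which participation
period), the adolescent-parent dyads, and the study-level constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time

ROLES = ("adolescent", "mother", "father")
PARENT_ROLES = ("mother", "father")

#: Default study-level iBeacon UUID (arbitrary; all beacons of one study share it).
DEFAULT_UUID = "f7826da6-4fa2-4e98-8024-bc5b71e0893e"


class RosterError(ValueError):
    """Raised when the roster violates a structural invariant."""


@dataclass(frozen=True, slots=True)
class ScanRecord:
    """One detection of a beacon by one observer phone.

    ``major`` identifies the beacon's family, ``minor`` the member within the
    family.  ``rssi`` is the received signal strength in dBm (non-positive).
    Records are immutable once read.
    """

    timestamp: datetime
    observer_device_id: str
    beacon_uuid: str
    major: int
    minor: int
    rssi: int
    beacon_name: str = ""

    def __post_init__(self) -> None:
        if self.major < 0 or self.minor < 0:
            raise ValueError("major and minor must be non-negative")

    def with_identity(self, major: int | None = None, minor: int | None = None) -> "ScanRecord":
        return replace(
            self,
            major=self.major if major is None else major,
            minor=self.minor if minor is None else minor,
        )


@dataclass(frozen=True, slots=True)
class BeaconAssignment:
    """One (major, minor) identity worn by a person over a date interval.

    Physical beacons were reused across the study, so one person may hold a
    sequence of assignments and one (major, minor) pair may belong to
    different persons at different dates.
    """

    major: int
    minor: int
    valid_from: date
    valid_to: date

    def __post_init__(self) -> None:
        if self.valid_to < self.valid_from:
            raise ValueError("assignment interval reversed")

    def active_on(self, day: date) -> bool:
        return self.valid_from <= day <= self.valid_to

    def overlaps(self, other: "BeaconAssignment") -> bool:
        return (
            self.major == other.major
            and self.minor == other.minor
            and self.valid_from <= other.valid_to
            and other.valid_from <= self.valid_to
        )


@dataclass(frozen=True)
class Participant:
    person_id: str
    family_id: str
    role: str
    device_ids: frozenset[str]
    beacon_assignments: tuple[BeaconAssignment, ...]
    participation_start: date
    participation_end: date

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise RosterError(f"unknown role {self.role!r}")
        if self.participation_end < self.participation_start:
            raise RosterError("participation end before start")

    def assignment_on(self, day: date) -> BeaconAssignment | None:
        for a in self.beacon_assignments:
            if a.active_on(day):
                return a
        return None

    def in_participation(self, day: date) -> bool:
        return self.participation_start <= day <= self.participation_end


@dataclass(frozen=True, slots=True)
class Dyad:
    """An adolescent paired with one parent: the unit of proximity measurement."""

    adolescent_id: str
    parent_id: str
    parent_role: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.adolescent_id, self.parent_id)


class Roster:
    """The study roster: participants with device and beacon bookkeeping.

    Validates on construction that beacon assignments for one (major, minor)
    identity never overlap in time across persons, that each device belongs to
    one person, and that each family has exactly one adolescent.
    """

    def __init__(self, participants: list[Participant]):
        self.participants: dict[str, Participant] = {}
        self.by_device: dict[str, Participant] = {}
        for p in participants:
            if p.person_id in self.participants:
                raise RosterError(f"duplicate person_id {p.person_id}")
            self.participants[p.person_id] = p
            for d in p.device_ids:
                if d in self.by_device:
                    raise RosterError(f"device {d} assigned to two persons")
                self.by_device[d] = p
        self._validate()

    def _validate(self) -> None:
        people = list(self.participants.values())
        for i, p in enumerate(people):
            for q in people[i + 1 :]:
                for a in p.beacon_assignments:
                    for b in q.beacon_assignments:
                        if a.overlaps(b):
                            raise RosterError(
                                f"beacon ({a.major},{a.minor}) assigned to both "
                                f"{p.person_id} and {q.person_id} over overlapping dates"
                            )
        by_family: dict[str, list[Participant]] = {}
        for p in people:
            by_family.setdefault(p.family_id, []).append(p)
        for fam, members in by_family.items():
            n_adol = sum(1 for m in members if m.role == "adolescent")
            if n_adol != 1:
                raise RosterError(f"family {fam} has {n_adol} adolescents, expected 1")
        self.families = by_family

    def __iter__(self):
        return iter(self.participants.values())

    def __len__(self) -> int:
        return len(self.participants)

    def get(self, person_id: str) -> Participant:
        return self.participants[person_id]

    def participant_for_device(self, device_id: str) -> Participant | None:
        return self.by_device.get(device_id)

    def wearer_at(self, major: int, minor: int, when: datetime) -> Participant | None:
        """The unique person wearing beacon (major, minor) at ``when``, or None."""
        day = when.date()
        matches = [
            p
            for p in self.participants.values()
            for a in p.beacon_assignments
            if a.major == major and a.minor == minor and a.active_on(day)
        ]
        if len(matches) > 1:  # pragma: no cover - excluded by _validate
            raise RosterError("overlapping beacon assignments")
        return matches[0] if matches else None

    def dyads(self) -> list[Dyad]:
        out: list[Dyad] = []
        for members in self.families.values():
            adol = next(m for m in members if m.role == "adolescent")
            for m in members:
                if m.role in PARENT_ROLES:
                    out.append(Dyad(adol.person_id, m.person_id, m.role))
        out.sort(key=lambda d: d.key)
        return out


@dataclass(frozen=True)
class StudyConfig:
    """Study-level constants, all durations in minutes.

    Defaults mirror the field deployment: ~5-min scan cycles, a 2.5-min
    two-sided merge window (half a cycle), a 7-min episode gap cutoff
    (~1.4 cycles), a 10-min minimum proximity before a departure can trigger
    a questionnaire, a 10-min post-departure trigger delay, a 4-h lockout,
    and a 30-min questionnaire expiry (10 min in legacy mode).  Daytime
    analysis windows are Mon-Fri 07:00-21:30 and Sat-Sun 09:00-23:00,
    inclusive at minute resolution.
    """

    uuid: str = DEFAULT_UUID
    scan_interval_min: float = 5.0
    merge_window_min: float = 2.5
    gap_cutoff_min: float = 7.0
    min_proximity_min: float = 10.0
    trigger_delay_min: float = 10.0
    lockout_min: float = 240.0
    expiry_min: float = 30.0
    legacy_expiry_min: float = 10.0
    weekday_window: tuple[time, time] = (time(7, 0), time(21, 30))
    weekend_window: tuple[time, time] = (time(9, 0), time(23, 0))
    tx_power_dbm: int = -20
    nominal_range_m: float = 4.0
    lockout_scope: str = "pair"  # "pair" (recipient,subject) or "recipient"

    def __post_init__(self) -> None:
        for name in (
            "scan_interval_min",
            "merge_window_min",
            "gap_cutoff_min",
            "min_proximity_min",
            "trigger_delay_min",
            "lockout_min",
            "expiry_min",
            "legacy_expiry_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for lo, hi in (self.weekday_window, self.weekend_window):
            if not lo < hi:
                raise ValueError("daytime window not well-ordered")
        if self.lockout_scope not in ("pair", "recipient"):
            raise ValueError("lockout_scope must be 'pair' or 'recipient'")
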