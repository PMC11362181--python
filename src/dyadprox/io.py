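"""Readers and writers for scan logs, rosters, and derived tables.

Scan logs are delimited text with a named header
(``timestamp,device_id,beacon_name,uuid,major,minor,rssi``); timestamps are
ISO-8601 in the single study timezone (stored naive).  The roster is one YAML
tree: families -> members, each with devices, beacon assignment intervals and
a participation period.  Reading is lossless: every input row is either
returned as a :class:`~dyadprox.types.ScanRecord` or counted in the audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path

import pandas as pd
import yaml

from .types import (
    BeaconAssignment,
    Participant,
    Roster,
    RosterError,
    ScanRecord,
    StudyConfig,
)

SCAN_COLUMNS = ["timestamp", "device_id", "beacon_name", "uuid", "major", "minor", "rssi"]


@dataclass
class ReadAudit:
    """Row accounting for one scan-log read: rows = returned + malformed."""

    rows: int = 0
    malformed: int = 0
    errors: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.errors is None:
            self.errors = []


def read_scan_log(path: str | Path) -> tuple[list[ScanRecord], ReadAudit]:
    """Read a scan log, returning records in timestamp order plus an audit.

    Rows with an unparseable timestamp or non-integer / negative major, minor
    are counted as malformed (with a row-level message), never silently
    dropped.  A missing mandatory column is a hard failure.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan log {path} missing mandatory columns: {missing}")

    audit = ReadAudit(rows=len(df))
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    records: list[ScanRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        t = ts.iloc[i]
        if pd.isna(t):
            audit.malformed += 1
            audit.errors.append(f"row {i}: unparseable timestamp {row.timestamp!r}")
            continue
        try:
            rec = ScanRecord(
                timestamp=t.to_pydatetime(),
                observer_device_id=str(row.device_id),
                beacon_uuid=str(row.uuid),
                major=int(row.major),
                minor=int(row.minor),
                rssi=int(float(row.rssi)),
                beacon_name=str(row.beacon_name),
            )
        except (TypeError, ValueError) as exc:
            audit.malformed += 1
            audit.errors.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    records.sort(key=lambda r: r.timestamp)
    return records, audit


def scan_records_to_frame(records: list[ScanRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [r.timestamp.isoformat(sep=" ") for r in records],
            "device_id": [r.observer_device_id for r in records],
            "beacon_name": [r.beacon_name for r in records],
            "uuid": [r.beacon_uuid for r in records],
            "major": [r.major for r in records],
            "minor": [r.minor for r in records],
            "rssi": [r.rssi for r in records],
        },
        columns=SCAN_COLUMNS,
    )


def write_scan_log(records: list[ScanRecord], path: str | Path) -> None:
    scan_records_to_frame(records).to_csv(path, index=False)


def resolve_identity(record: ScanRecord, roster: Roster) -> str | None:
    """Person wearing the detected beacon at the record's timestamp, or None.

    The roster guarantees at most one active assignment per (major, minor)
    identity at any date, so the lookup is a function.
    """
    wearer = roster.wearer_at(record.major, record.minor, record.timestamp)
    return wearer.person_id if wearer else None


# --- roster / config YAML ---------------------------------------------------


def _as_date(v) -> date:
    if isinstance(v, datetime):
        return v.date()
    if isinstance(v, date):
        return v
    return date.fromisoformat(str(v))


def load_roster(path: str | Path) -> tuple[Roster, StudyConfig]:
    """Load the roster + study config from one YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg_raw = dict(doc.get("study", {}))
    cfg_kwargs = {}
    for key in (
        "uuid",
        "scan_interval_min",
        "merge_window_min",
        "gap_cutoff_min",
        "min_proximity_min",
        "trigger_delay_min",
        "lockout_min",
        "expiry_min",
        "legacy_expiry_min",
        "tx_power_dbm",
        "nominal_range_m",
        "lockout_scope",
    ):
        if key in cfg_raw:
            cfg_kwargs[key] = cfg_raw[key]
    config = StudyConfig(**cfg_kwargs)

    participants: list[Participant] = []
    for family_id, fam in doc.get("families", {}).items():
        for member in fam.get("members", []):
            part = member["participation"]
            assignments = tuple(
                BeaconAssignment(
                    major=int(b["major"]),
                    minor=int(b["minor"]),
                    valid_from=_as_date(b["from"]),
                    valid_to=_as_date(b["to"]),
                )
                for b in member.get("beacons", [])
            )
            participants.append(
                Participant(
                    person_id=str(member["person_id"]),
                    family_id=str(family_id),
                    role=str(member["role"]),
                    device_ids=frozenset(str(d) for d in member.get("devices", [])),
                    beacon_assignments=assignments,
                    participation_start=_as_date(part["start"]),
                    participation_end=_as_date(part["end"]),
                )
            )
    if not participants:
        raise RosterError(f"roster {path} contains no participants")
    return Roster(participants), config


def save_roster(roster: Roster, config: StudyConfig, path: str | Path) -> None:
    doc: dict = {
        "study": {
            "uuid": config.uuid,
            "scan_interval_min": config.scan_interval_min,
            "merge_window_min": config.merge_window_min,
            "gap_cutoff_min": config.gap_cutoff_min,
            "min_proximity_min": config.min_proximity_min,
            "trigger_delay_min": config.trigger_delay_min,
            "lockout_min": config.lockout_min,
            "expiry_min": config.expiry_min,
            "legacy_expiry_min": config.legacy_expiry_min,
            "tx_power_dbm": config.tx_power_dbm,
            "nominal_range_m": config.nominal_range_m,
            "lockout_scope": config.lockout_scope,
        },
        "families": {},
    }
    for family_id in sorted(roster.families):
        members = []
        for p in sorted(roster.families[family_id], key=lambda p: p.person_id):
            members.append(
                {
                    "person_id": p.person_id,
                    "role": p.role,
                    "devices": sorted(p.device_ids),
                    "participation": {
                        "start": p.participation_start.isoformat(),
                        "end": p.participation_end.isoformat(),
                    },
                    "beacons": [
                        {
                            "major": a.major,
                            "minor": a.minor,
                            "from": a.valid_from.isoformat(),
                            "to": a.valid_to.isoformat(),
                        }
                        for a in p.beacon_assignments
                    ],
                }
            )
        doc["families"][family_id] = {"members": members}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
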