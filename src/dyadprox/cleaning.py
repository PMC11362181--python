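"""Five-step cleaning of raw beacon scan logs with a full row audit.

The steps run in a fixed order so audits are comparable across runs:

1. drop records from pilot-phase test-account devices;
2. drop records involving excluded families (observer or detected beacon);
3. repair retraceable major/minor identity errors (beacon-reuse artifacts);
4. drop records whose observer and beacon wearer are not two distinct
   members of the same roster family (cross-family detections, unresolvable
   identities, self-detections, unknown devices);
5. clip to the observer's participation period (inclusive date bounds).

Every removed row is counted under exactly one audit field, so
``rows_out = rows_in - sum(removed_*)`` holds exactly.  Cleaning is
idempotent and never invents records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import resolve_identity
from .types import Participant, Roster, ScanRecord


@dataclass
class CleaningAudit:
    rows_in: int = 0
    removed_test_accounts: int = 0
    removed_excluded_families: int = 0
    repaired_identity: int = 0
    unrepairable_identity: int = 0
    removed_out_of_roster: int = 0
    removed_out_of_period: int = 0
    rows_out: int = 0

    @property
    def removed_total(self) -> int:
        return (
            self.removed_test_accounts
            + self.removed_excluded_families
            + self.removed_out_of_roster
            + self.removed_out_of_period
        )

    def check(self) -> None:
        assert self.rows_out == self.rows_in - self.removed_total

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rows_in": self.rows_in,
                    "removed_test_accounts": self.removed_test_accounts,
                    "removed_excluded_families": self.removed_excluded_families,
                    "repaired_identity": self.repaired_identity,
                    "unrepairable_identity": self.unrepairable_identity,
                    "removed_out_of_roster": self.removed_out_of_roster,
                    "removed_out_of_period": self.removed_out_of_period,
                    "rows_out": self.rows_out,
                }
            ]
        )


def repair_identity(
    record: ScanRecord, roster: Roster, observer: Participant | None = None
) -> ScanRecord | None:
    """Attempt to repair a record that failed identity resolution.

    Beacon reuse leaves records whose major/minor disagree with the roster
    (e.g. a stale minor after a reconfiguration did not synchronise).  A
    repair is made only when exactly one roster assignment — excluding the
    observer's own beacons, which their phone does not report — agrees with
    the record on at least two of {major, minor, observer-family,
    date-in-assignment-window} while disagreeing on exactly one of
    {major, minor}.  Ambiguous records are never guessed at.
    """
    if observer is None:
        observer = roster.participant_for_device(record.observer_device_id)
    day = record.timestamp.date()
    candidates: list[tuple[Participant, int | None, int | None]] = []
    for p in roster:
        if observer is not None and p.person_id == observer.person_id:
            continue
        for a in p.beacon_assignments:
            major_ok = a.major == record.major
            minor_ok = a.minor == record.minor
            mismatches = int(not major_ok) + int(not minor_ok)
            if mismatches != 1:
                continue
            agreements = int(major_ok) + int(minor_ok)
            agreements += int(observer is not None and p.family_id == observer.family_id)
            agreements += int(a.active_on(day))
            if agreements >= 2:
                candidates.append(
                    (
                        p,
                        a.major if not major_ok else None,
                        a.minor if not minor_ok else None,
                    )
                )
    # distinct assignments of one person may propose the same fix; dedupe
    unique = {(p.person_id, mj, mn) for p, mj, mn in candidates}
    if len(unique) != 1:
        return None
    _, major_fix, minor_fix = next(iter(unique))
    return record.with_identity(major=major_fix, minor=minor_fix)


def clip_to_period(
    records: list[ScanRecord], roster: Roster
) -> tuple[list[ScanRecord], int, int]:
    """Keep records dated inside the observer's participation period.

    Bounds are inclusive at date granularity.  Returns (kept, n_out_of_period,
    n_unknown_observer).
    """
    kept: list[ScanRecord] = []
    out_of_period = 0
    unknown = 0
    for r in records:
        obs = roster.participant_for_device(r.observer_device_id)
        if obs is None:
            unknown += 1
            continue
        if obs.in_participation(r.timestamp.date()):
            kept.append(r)
        else:
            out_of_period += 1
    return kept, out_of_period, unknown


def clean(
    records: list[ScanRecord],
    roster: Roster,
    test_accounts: set[str] | frozenset[str] = frozenset(),
    excluded_families: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[ScanRecord], CleaningAudit]:
    """Run the five cleaning steps; all anomalies are audited, never fatal."""
    audit = CleaningAudit(rows_in=len(records))

    # 1. test accounts
    step1 = [r for r in records if r.observer_device_id not in test_accounts]
    audit.removed_test_accounts = len(records) - len(step1)

    # 2. excluded families (either side of the detection)
    step2: list[ScanRecord] = []
    for r in step1:
        obs = roster.participant_for_device(r.observer_device_id)
        wearer_id = resolve_identity(r, roster)
        wearer = roster.get(wearer_id) if wearer_id else None
        if (obs is not None and obs.family_id in excluded_families) or (
            wearer is not None and wearer.family_id in excluded_families
        ):
            audit.removed_excluded_families += 1
        else:
            step2.append(r)

    # 3. identity repair for records that resolve to no wearer
    step3: list[ScanRecord] = []
    for r in step2:
        if resolve_identity(r, roster) is not None:
            step3.append(r)
            continue
        fixed = repair_identity(r, roster)
        if fixed is not None:
            audit.repaired_identity += 1
            step3.append(fixed)
        else:
            audit.unrepairable_identity += 1
            step3.append(r)  # removed (and counted) in step 4

    # 4. out-of-roster: keep only within-family detections of another member
    step4: list[ScanRecord] = []
    for r in step3:
        obs = roster.participant_for_device(r.observer_device_id)
        wearer_id = resolve_identity(r, roster)
        wearer = roster.get(wearer_id) if wearer_id else None
        if (
            obs is None
            or wearer is None
            or wearer.family_id != obs.family_id
            or wearer.person_id == obs.person_id
        ):
            audit.removed_out_of_roster += 1
        else:
            step4.append(r)

    # 5. participation period of the observer
    step5, out_of_period, unknown = clip_to_period(step4, roster)
    audit.removed_out_of_period = out_of_period
    audit.removed_out_of_roster += unknown  # unreachable after step 4; kept for safety

    audit.rows_out = len(step5)
    audit.check()
    return step5, audit
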