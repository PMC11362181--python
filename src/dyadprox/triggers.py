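"""Event-contingent questionnaire triggering over dyadic occurrence streams.

A dyad that has been in proximity for at least 10 minutes and then departs
receives a questionnaire 10 minutes after departure.  Departure is
operationalized as the last detection followed by silence longer than the
episode gap cutoff; the timer starts at that last detection and a reappearing
occurrence before the scheduled fire time cancels the trigger.  A fired
trigger blocks further triggers for the same recipient-subject pair for the
next 4 hours.  Each dyadic departure is evaluated independently for the two
recipients (the adolescent gets separate mother/father questionnaires; each
parent gets one about the adolescent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .proximity import Occurrence
from .types import StudyConfig

STATUSES = ("fired", "canceled_by_reapproach", "suppressed_by_lockout")
Q_STATUSES = ("completed", "expired", "canceled", "n/a")


@dataclass(frozen=True, slots=True)
class TriggerEvent:
    recipient: str
    subject: str
    recipient_group: str  # "adolescent" or "parent"
    parent_role: str  # role of the parent in the dyad (mother/father)
    proximity_start: datetime
    departure_time: datetime
    scheduled_fire: datetime
    status: str
    questionnaire_status: str = "n/a"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.recipient, self.subject)


def _round(x: float, ndigits: int) -> float:
    """Half-up decimal rounding, as printed in study reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def simulate_triggers(
    occurrences: list[Occurrence], config: StudyConfig
) -> list[TriggerEvent]:
    """Replay the trigger logic over windowed, merged occurrences.

    For each maximal occurrence run (gaps <= gap cutoff) ending at
    ``departure``, a trigger is scheduled iff the run spans at least
    ``min_proximity`` minutes.  It fires at ``departure + trigger_delay``
    unless a new dyad occurrence appears in (departure, fire] (canceled by
    reapproach) or a previously fired trigger for the same pair is younger
    than the lockout (suppressed).  Deterministic: identical streams yield
    identical event sequences.
    """
    gap = timedelta(minutes=config.gap_cutoff_min)
    delay = timedelta(minutes=config.trigger_delay_min)
    min_prox = timedelta(minutes=config.min_proximity_min)
    lockout = timedelta(minutes=config.lockout_min)

    by_dyad: dict[tuple[str, str], list[Occurrence]] = {}
    for o in occurrences:
        by_dyad.setdefault(o.dyad.key, []).append(o)

    # candidate (per-recipient) events across all dyads, then resolve lockouts
    # in global fire-time order so recipient-scoped lockouts couple correctly.
    candidates: list[TriggerEvent] = []
    for key in sorted(by_dyad):
        occs = sorted(by_dyad[key], key=lambda o: o.timestamp)
        dyad = occs[0].dyad
        runs: list[list[Occurrence]] = [[occs[0]]]
        for o in occs[1:]:
            if o.timestamp - runs[-1][-1].timestamp <= gap:
                runs[-1].append(o)
            else:
                runs.append([o])
        next_start = [r[0].timestamp for r in runs[1:]] + [None]
        for run, nxt in zip(runs, next_start):
            start, departure = run[0].timestamp, run[-1].timestamp
            if departure - start < min_prox:
                continue
            fire = departure + delay
            reapproached = nxt is not None and departure < nxt <= fire
            for recipient, subject, group in (
                (dyad.adolescent_id, dyad.parent_id, "adolescent"),
                (dyad.parent_id, dyad.adolescent_id, "parent"),
            ):
                candidates.append(
                    TriggerEvent(
                        recipient=recipient,
                        subject=subject,
                        recipient_group=group,
                        parent_role=dyad.parent_role,
                        proximity_start=start,
                        departure_time=departure,
                        scheduled_fire=fire,
                        status="canceled_by_reapproach" if reapproached else "fired",
                    )
                )

    candidates.sort(key=lambda e: (e.scheduled_fire, e.recipient, e.subject))
    last_fired: dict[tuple, datetime] = {}
    events: list[TriggerEvent] = []
    for ev in candidates:
        if ev.status == "fired":
            scope = ev.recipient if config.lockout_scope == "recipient" else ev.pair
            prev = last_fired.get(scope)
            if prev is not None and ev.scheduled_fire - prev < lockout:
                ev = replace(ev, status="suppressed_by_lockout")
            else:
                last_fired[scope] = ev.scheduled_fire
        events.append(ev)
    return events


def resolve_questionnaire(
    event: TriggerEvent, response_log: pd.DataFrame, config: StudyConfig, legacy: bool = False
) -> str:
    """Lifecycle status of one fired questionnaire against the response log.

    completed: submitted within the expiry window after the fire time;
    canceled: started within expiry but not finished in time;
    expired: no response activity within expiry.
    """
    if event.status != "fired":
        return "n/a"
    expiry = timedelta(minutes=config.legacy_expiry_min if legacy else config.expiry_min)
    deadline = event.scheduled_fire + expiry
    rows = response_log[
        (response_log["recipient"] == event.recipient)
        & (response_log["subject"] == event.subject)
        & (response_log["fired_time"] == event.scheduled_fire.isoformat(sep=" "))
    ]
    status = "expired"
    for row in rows.itertuples(index=False):
        started = pd.Timestamp(row.started_time) if row.started_time else pd.NaT
        submitted = pd.Timestamp(row.submitted_time) if row.submitted_time else pd.NaT
        if pd.notna(submitted):
            if submitted.to_pydatetime() < event.scheduled_fire:
                raise ValueError("response submitted before questionnaire fired")
            if submitted.to_pydatetime() <= deadline:
                return "completed"
        if pd.notna(started) and event.scheduled_fire <= started.to_pydatetime() <= deadline:
            status = "canceled"
    return status


def resolve_all(
    events: list[TriggerEvent], response_log: pd.DataFrame, config: StudyConfig, legacy: bool = False
) -> list[TriggerEvent]:
    return [
        replace(ev, questionnaire_status=resolve_questionnaire(ev, response_log, config, legacy))
        if ev.status == "fired"
        else ev
        for ev in events
    ]


def compliance_summary(events: list[TriggerEvent], group: str) -> dict:
    """Delivery/completion accounting for one recipient group.

    ``group`` is "adolescents" or "parents".  Percentages are completed /
    delivered on the 0-100 scale, one decimal; per-recipient means divide
    delivered by the number of recipients with at least one delivery, two
    decimals.  With zero deliveries the percentages are NaN, never 0.
    """
    want = {"adolescents": "adolescent", "parents": "parent"}[group]
    fired = [e for e in events if e.status == "fired" and e.recipient_group == want]
    delivered = len(fired)
    completed = sum(1 for e in fired if e.questionnaire_status == "completed")
    canceled = sum(1 for e in fired if e.questionnaire_status == "canceled")
    expired = sum(1 for e in fired if e.questionnaire_status == "expired")

    per_recipient: dict[str, int] = {}
    for e in fired:
        per_recipient[e.recipient] = per_recipient.get(e.recipient, 0) + 1
    counts = np.array(sorted(per_recipient.values()), dtype=float)

    out = {
        "group": group,
        "delivered": delivered,
        "completed": completed,
        "canceled": canceled,
        "expired": expired,
        "pct_completed": _round(100.0 * completed / delivered, 1) if delivered else math.nan,
        "n_recipients": len(per_recipient),
        "mean_delivered": _round(delivered / len(per_recipient), 2) if per_recipient else math.nan,
        "sd_delivered": float(counts.std(ddof=1)) if len(counts) > 1 else math.nan,
        "min_delivered": int(counts.min()) if len(counts) else 0,
        "max_delivered": int(counts.max()) if len(counts) else 0,
    }
    if group == "adolescents":
        for role in ("mother", "father"):
            sub = [e for e in fired if e.parent_role == role]
            dsub = len(sub)
            csub = sum(1 for e in sub if e.questionnaire_status == "completed")
            out[f"delivered_{role}"] = dsub
            out[f"completed_{role}"] = csub
            out[f"pct_completed_{role}"] = (
                _round(100.0 * csub / dsub, 1) if dsub else math.nan
            )
            out[f"pct_delivered_{role}"] = (
                _round(100.0 * dsub / delivered, 1) if delivered else math.nan
            )
    return out


def events_to_frame(events: list[TriggerEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "recipient": [e.recipient for e in events],
            "subject": [e.subject for e in events],
            "recipient_group": [e.recipient_group for e in events],
            "parent_role": [e.parent_role for e in events],
            "proximity_start": [e.proximity_start.isoformat(sep=" ") for e in events],
            "departure_time": [e.departure_time.isoformat(sep=" ") for e in events],
            "scheduled_fire": [e.scheduled_fire.isoformat(sep=" ") for e in events],
            "status": [e.status for e in events],
            "questionnaire_status": [e.questionnaire_status for e in events],
        }
    )
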