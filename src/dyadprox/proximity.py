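"""Dyadic occurrences, episodes, and frequency/duration metrics.

The sensing is two-sided: the adolescent's phone scans for the parent's
beacon and vice versa.  Near-simultaneous detections from opposite sides
(within the 2.5-min merge window) are merged into a single *occurrence*,
stamped with the adolescent-side timestamp.  A maximal run of occurrences
whose successive gaps stay within the 7-min cutoff forms an *episode*; its
duration is the sum of those gaps, so an isolated detection contributes no
duration.  Analyses are restricted to daytime windows (Mon-Fri 07:00-21:30,
Sat-Sun 09:00-23:00, inclusive at minute resolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta
from statistics import median

import pandas as pd

from .io import resolve_identity
from .types import Dyad, Roster, ScanRecord, StudyConfig

SIDES = ("adolescent_only", "parent_only", "both")


@dataclass(frozen=True, slots=True)
class Occurrence:
    """One dyad-level proximity detection after two-sided merging."""

    dyad: Dyad
    timestamp: datetime
    sides: str  # adolescent_only | parent_only | both
    n_sources: int = 1


@dataclass(frozen=True, slots=True)
class Episode:
    """A maximal run of >=2 occurrences with inter-scan gaps <= the cutoff."""

    dyad: Dyad
    start: datetime
    end: datetime
    n_occurrences: int

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


def _minutes(a: datetime, b: datetime) -> float:
    return abs((a - b).total_seconds()) / 60.0


def in_daytime(ts: datetime, config: StudyConfig) -> bool:
    """True if ``ts`` falls inside the daytime analysis window for its day."""
    lo, hi = config.weekday_window if ts.weekday() < 5 else config.weekend_window
    t = time(ts.hour, ts.minute)  # inclusive bounds at minute resolution
    return lo <= t <= hi


def apply_daytime_window(items, config: StudyConfig, key=None):
    """Filter records/occurrences to daytime; idempotent by construction."""
    if key is None:
        key = lambda x: x.timestamp  # noqa: E731
    return [x for x in items if in_daytime(key(x), config)]


def dedup_scans(
    records: list[ScanRecord], window_min: float = 1.0
) -> tuple[list[ScanRecord], int]:
    """Collapse repeated broadcasts of one beacon within one scan cycle.

    A device may log several advertisements of the same beacon within a
    single ~5-min scan; detections of the same (device, beacon identity)
    within ``window_min`` of the last kept record collapse into it.  Returns
    (kept, n_collapsed).
    """
    last: dict[tuple[str, str, int, int], datetime] = {}
    kept: list[ScanRecord] = []
    collapsed = 0
    for r in sorted(records, key=lambda r: (r.timestamp, r.observer_device_id, r.major, r.minor)):
        k = (r.observer_device_id, r.beacon_uuid, r.major, r.minor)
        prev = last.get(k)
        if prev is not None and _minutes(r.timestamp, prev) < window_min:
            collapsed += 1
            continue
        last[k] = r.timestamp
        kept.append(r)
    return kept, collapsed


def merge_two_sided(
    adolescent_side: list[datetime],
    parent_side: list[datetime],
    merge_window_min: float,
) -> list[tuple[datetime, str]]:
    """Greedy chronological one-to-one pairing of two-sided detections.

    Walks both sorted streams in time order; the earliest unpaired scans from
    opposite sides with |dt| <= merge window pair into one ``both`` occurrence
    stamped with the adolescent-side time; anything unpaired emits a
    one-sided occurrence.  Returns (timestamp, sides) sorted by time.
    """
    for seq in (adolescent_side, parent_side):
        if any(seq[i] > seq[i + 1] for i in range(len(seq) - 1)):
            raise ValueError("merge_two_sided requires sorted inputs")
    out: list[tuple[datetime, str]] = []
    i = j = 0
    na, np_ = len(adolescent_side), len(parent_side)
    while i < na and j < np_:
        a, p = adolescent_side[i], parent_side[j]
        if _minutes(a, p) <= merge_window_min:
            out.append((a, "both"))
            i += 1
            j += 1
        elif a <= p:
            out.append((a, "adolescent_only"))
            i += 1
        else:
            out.append((p, "parent_only"))
            j += 1
    out.extend((t, "adolescent_only") for t in adolescent_side[i:])
    out.extend((t, "parent_only") for t in parent_side[j:])
    out.sort(key=lambda x: x[0])
    return out


def dyad_sides(
    records: list[ScanRecord], roster: Roster, dyad: Dyad
) -> tuple[list[datetime], list[datetime]]:
    """Split cleaned records into adolescent-side and parent-side detections."""
    adol = roster.get(dyad.adolescent_id)
    parent = roster.get(dyad.parent_id)
    a_times: list[datetime] = []
    p_times: list[datetime] = []
    for r in records:
        obs = roster.participant_for_device(r.observer_device_id)
        if obs is None:
            continue
        wearer = resolve_identity(r, roster)
        if obs.person_id == adol.person_id and wearer == parent.person_id:
            a_times.append(r.timestamp)
        elif obs.person_id == parent.person_id and wearer == adol.person_id:
            p_times.append(r.timestamp)
    a_times.sort()
    p_times.sort()
    return a_times, p_times


def build_occurrences(
    records: list[ScanRecord],
    roster: Roster,
    config: StudyConfig,
    dedup_window_min: float = 1.0,
) -> tuple[list[Occurrence], int]:
    """Cleaned records -> per-dyad merged occurrences (not yet windowed).

    Returns (occurrences sorted by dyad then time, n_collapsed_broadcasts).
    """
    deduped, collapsed = dedup_scans(records, dedup_window_min)
    occurrences: list[Occurrence] = []
    for dyad in roster.dyads():
        a_times, p_times = dyad_sides(deduped, roster, dyad)
        for ts, sides in merge_two_sided(a_times, p_times, config.merge_window_min):
            occurrences.append(
                Occurrence(dyad, ts, sides, n_sources=2 if sides == "both" else 1)
            )
    occurrences.sort(key=lambda o: (o.dyad.key, o.timestamp))
    return occurrences, collapsed


def build_episodes(
    occurrences: list[Occurrence], gap_cutoff_min: float
) -> list[Episode]:
    """Segment per-dyad occurrence streams into maximal episodes.

    Successive gaps <= cutoff (inclusive) extend a run; runs of length 1
    yield no episode.  Input must be windowed and merged.
    """
    episodes: list[Episode] = []
    by_dyad: dict[tuple[str, str], list[Occurrence]] = {}
    for o in occurrences:
        by_dyad.setdefault(o.dyad.key, []).append(o)
    for key in sorted(by_dyad):
        occs = sorted(by_dyad[key], key=lambda o: o.timestamp)
        run: list[Occurrence] = [occs[0]]
        for o in occs[1:]:
            if _minutes(o.timestamp, run[-1].timestamp) <= gap_cutoff_min:
                run.append(o)
            else:
                if len(run) >= 2:
                    episodes.append(
                        Episode(run[0].dyad, run[0].timestamp, run[-1].timestamp, len(run))
                    )
                run = [o]
        if len(run) >= 2:
            episodes.append(Episode(run[0].dyad, run[0].timestamp, run[-1].timestamp, len(run)))
    return episodes


def _day_counts(start, end, config: StudyConfig) -> tuple[int, int]:
    """(weekdays, weekend days) in [start, end] inclusive."""
    wk = we = 0
    d = start
    while d <= end:
        if d.weekday() < 5:
            wk += 1
        else:
            we += 1
        d += timedelta(days=1)
    return wk, we


def compute_metrics(
    episodes: list[Episode],
    occurrences: list[Occurrence],
    roster: Roster,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-dyad frequency and duration metrics over the participation window.

    Per-day denominators are all calendar days of the dyad's participation
    window (weekday/weekend split by calendar day type), not only days with
    data: absent detections are informative.  Dyads with zero data get a
    zero row with ``no_data=True`` rather than being dropped.
    """
    occ_by_dyad: dict[tuple[str, str], list[Occurrence]] = {}
    for o in occurrences:
        occ_by_dyad.setdefault(o.dyad.key, []).append(o)
    ep_by_dyad: dict[tuple[str, str], list[Episode]] = {}
    for e in episodes:
        ep_by_dyad.setdefault(e.dyad.key, []).append(e)

    rows = []
    for dyad in roster.dyads():
        adol = roster.get(dyad.adolescent_id)
        start, end = adol.participation_start, adol.participation_end
        n_weekday, n_weekend = _day_counts(start, end, config)
        n_days = n_weekday + n_weekend

        occs = occ_by_dyad.get(dyad.key, [])
        eps = ep_by_dyad.get(dyad.key, [])
        freq_total = len(occs)
        freq_weekday = sum(1 for o in occs if o.timestamp.weekday() < 5)
        freq_weekend = freq_total - freq_weekday
        dur_total = sum(e.duration_min for e in eps)
        dur_weekday = sum(e.duration_min for e in eps if e.start.weekday() < 5)
        dur_weekend = dur_total - dur_weekday
        durations = [e.duration_min for e in eps]

        rows.append(
            {
                "adolescent_id": dyad.adolescent_id,
                "parent_id": dyad.parent_id,
                "parent_role": dyad.parent_role,
                "family_id": adol.family_id,
                "freq_total": freq_total,
                "freq_episodes": len(eps),
                "freq_per_day": freq_total / n_days if n_days else 0.0,
                "freq_weekday": freq_weekday / n_weekday if n_weekday else 0.0,
                "freq_weekend": freq_weekend / n_weekend if n_weekend else 0.0,
                "dur_total_min": dur_total,
                "dur_per_day_min": dur_total / n_days if n_days else 0.0,
                "dur_weekday_min": dur_weekday / n_weekday if n_weekday else 0.0,
                "dur_weekend_min": dur_weekend / n_weekend if n_weekend else 0.0,
                "moment_median_min": median(durations) if durations else 0.0,
                "n_days": n_days,
                "no_data": freq_total == 0,
            }
        )
    return pd.DataFrame(rows)


def hourly_profile(
    occurrences: list[Occurrence], roster: Roster, per_family: bool = False
) -> pd.DataFrame:
    """Occurrence counts by (weekday, hour, parent_role), averaged over dyads.

    ``total`` conserves the occurrence count (sums to len(occurrences));
    ``mean_per_dyad`` divides by the number of roster dyads with that parent
    role.  With ``per_family=True`` counts are additionally split by family.
    """
    n_dyads = {
        role: sum(1 for d in roster.dyads() if d.parent_role == role)
        for role in ("mother", "father")
    }
    rows: dict[tuple, int] = {}
    for o in occurrences:
        key: tuple
        key = (o.timestamp.weekday(), o.timestamp.hour, o.dyad.parent_role)
        if per_family:
            key = key + (roster.get(o.dyad.adolescent_id).family_id,)
        rows[key] = rows.get(key, 0) + 1
    cols = ["weekday", "hour", "parent_role"] + (["family_id"] if per_family else [])
    out = pd.DataFrame([list(k) + [v] for k, v in sorted(rows.items())], columns=cols + ["total"])
    if not per_family and not out.empty:
        out["mean_per_dyad"] = out.apply(
            lambda r: r["total"] / n_dyads[r["parent_role"]] if n_dyads[r["parent_role"]] else 0.0,
            axis=1,
        )
    return out


def occurrences_to_frame(occurrences: list[Occurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "adolescent_id": [o.dyad.adolescent_id for o in occurrences],
            "parent_id": [o.dyad.parent_id for o in occurrences],
            "parent_role": [o.dyad.parent_role for o in occurrences],
            "timestamp": [o.timestamp.isoformat(sep=" ") for o in occurrences],
            "sides": [o.sides for o in occurrences],
        }
    )


def occurrences_from_frame(df: pd.DataFrame) -> list[Occurrence]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Occurrence(
                Dyad(str(row.adolescent_id), str(row.parent_id), str(row.parent_role)),
                pd.Timestamp(row.timestamp).to_pydatetime(),
                str(row.sides),
            )
        )
    out.sort(key=lambda o: (o.dyad.key, o.timestamp))
    return out


def episodes_to_frame(episodes: list[Episode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "adolescent_id": [e.dyad.adolescent_id for e in episodes],
            "parent_id": [e.dyad.parent_id for e in episodes],
            "parent_role": [e.dyad.parent_role for e in episodes],
            "start": [e.start.isoformat(sep=" ") for e in episodes],
            "end": [e.end.isoformat(sep=" ") for e in episodes],
            "duration_min": [e.duration_min for e in episodes],
            "n_occurrences": [e.n_occurrences for e in episodes],
        }
    )
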