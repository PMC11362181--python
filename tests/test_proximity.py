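"""Daytime windowing, two-sided merging, episode segmentation, and metrics.

Merging and segmentation are checked against independent brute-force oracles:
exhaustive maximum one-to-one pairing for the merge, and exhaustive
enumeration of all run splits for episodes.
"""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ts
from dyadprox.proximity import (
    Occurrence,
    apply_daytime_window,
    build_episodes,
    build_occurrences,
    compute_metrics,
    dedup_scans,
    hourly_profile,
    in_daytime,
    merge_two_sided,
)
from dyadprox.types import Dyad, ScanRecord


# --- independent oracles ------------------------------------------------------


def max_pairing_count(a_times, p_times, window_min):
    """Brute-force maximum one-to-one pairing with |dt| <= window (exhaustive)."""

    def best(i, used):
        if i == len(a_times):
            return 0
        score = best(i + 1, used)  # leave a_times[i] unpaired
        for j, p in enumerate(p_times):
            if j in used:
                continue
            if abs((a_times[i] - p).total_seconds()) / 60.0 <= window_min:
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())


def brute_force_episodes(times, gap_cutoff_min):
    """Enumerate all split points; the valid segmentation (within-run gaps <=
    cutoff, between-run gaps > cutoff) is unique. Returns run index lists."""
    n = len(times)
    if n == 0:
        return []
    valid = []
    for mask in range(2 ** max(n - 1, 0)):
        runs, run = [], [0]
        ok = True
        for i in range(1, n):
            gap = (times[i] - times[i - 1]).total_seconds() / 60.0
            if mask & (1 << (i - 1)):  # split before i
                if gap <= gap_cutoff_min:
                    ok = False
                    break
                runs.append(run)
                run = [i]
            else:
                if gap > gap_cutoff_min:
                    ok = False
                    break
                run.append(i)
        if ok:
            runs.append(run)
            valid.append(runs)
    assert len(valid) == 1
    return valid[0]


# --- daytime window -----------------------------------------------------------


@pytest.mark.parametrize(
    "when,kept",
    [
        (ts(2, 6, 59), False),  # Tuesday before 07:00
        (ts(2, 7, 0), True),  # Tuesday at 07:00 (inclusive)
        (ts(2, 21, 30), True),  # Tuesday at 21:30 (inclusive)
        (ts(2, 21, 31), False),
        (ts(6, 8, 59), False),  # Saturday before 09:00
        (ts(6, 9, 0), True),
        (ts(6, 22, 30), True),  # Saturday evening kept
        (ts(6, 23, 0), True),  # Saturday at 23:00 (inclusive)
        (ts(6, 23, 1), False),
    ],
)
def test_daytime_window_boundaries(config, when, kept):
    assert in_daytime(when, config) is kept


def test_daytime_filter_idempotent(config):
    times = [ts(d, h) for d in range(1, 8) for h in range(24)]
    once = apply_daytime_window(times, config, key=lambda t: t)
    twice = apply_daytime_window(once, config, key=lambda t: t)
    assert twice == once


# --- two-sided merge ----------------------------------------------------------


class TestMergeTwoSided:
    def test_two_sided_pair_is_one_occurrence_at_adolescent_time(self):
        out = merge_two_sided([ts(1, 10, 0)], [ts(1, 10, 2)], 2.5)
        assert out == [(ts(1, 10, 0), "both")]

    def test_one_sided_detection_kept(self):
        assert merge_two_sided([ts(1, 10, 0)], [], 2.5) == [(ts(1, 10, 0), "adolescent_only")]

    def test_interleaved_scans_pair_one_to_one(self):
        a = [ts(1, 10, 0), ts(1, 10, 5)]
        p = [ts(1, 10, 2), ts(1, 10, 6)]
        out = merge_two_sided(a, p, 2.5)
        assert [s for _, s in out] == ["both", "both"]
        assert [t for t, _ in out] == a  # stamped with adolescent-side times
        assert len(out) == 2  # counted as 2 occurrences, not 4

    def test_beyond_window_not_merged(self):
        out = merge_two_sided([ts(1, 10, 0)], [ts(1, 10, 2, 31)], 2.5)
        assert [s for _, s in out] == ["adolescent_only", "parent_only"]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_two_sided([ts(1, 10, 5), ts(1, 10, 0)], [], 2.5)

    @settings(max_examples=200, deadline=None)
    @given(
        a_offsets=st.lists(st.integers(0, 120), max_size=6),
        p_offsets=st.lists(st.integers(0, 120), max_size=6),
    )
    def test_pair_count_matches_bruteforce_maximum(self, a_offsets, p_offsets):
        base = ts(1, 10, 0)
        a = sorted(base + timedelta(minutes=o) for o in a_offsets)
        p = sorted(base + timedelta(minutes=o) for o in p_offsets)
        out = merge_two_sided(a, p, 2.5)
        n_both = sum(1 for _, s in out if s == "both")
        assert n_both == max_pairing_count(a, p, 2.5)
        # conservation of scans: both consumes one from each side
        assert len(out) == len(a) + len(p) - n_both

    @settings(max_examples=100, deadline=None)
    @given(
        a_offsets=st.lists(st.integers(0, 400), max_size=8),
        p_offsets=st.lists(st.integers(0, 400), max_size=8),
    )
    def test_occurrence_count_bounds(self, a_offsets, p_offsets):
        base = ts(1, 10, 0)
        a = sorted(base + timedelta(minutes=o) for o in a_offsets)
        p = sorted(base + timedelta(minutes=o) for o in p_offsets)
        total = len(merge_two_sided(a, p, 2.5))
        assert max(len(a), len(p)) <= total <= len(a) + len(p)


# --- episodes -----------------------------------------------------------------


def occ(minutes, dyad=None):
    dyad = dyad or Dyad("a", "m", "mother")
    base = ts(1, 10, 0)
    return [
        Occurrence(dyad, base + timedelta(minutes=m), "both") for m in minutes
    ]


class TestBuildEpisodes:
    def test_consecutive_scans_sum_gaps(self):
        eps = build_episodes(occ([0, 5, 10]), 7.0)
        assert len(eps) == 1
        assert eps[0].duration_min == 10.0
        assert eps[0].n_occurrences == 3

    def test_gap_beyond_cutoff_splits(self):
        eps = build_episodes(occ([0, 5, 13, 18]), 7.0)
        assert [e.duration_min for e in eps] == [5.0, 5.0]

    def test_gap_exactly_at_cutoff_keeps_run(self):
        eps = build_episodes(occ([0, 7]), 7.0)
        assert len(eps) == 1 and eps[0].duration_min == 7.0

    def test_isolated_occurrence_contributes_nothing(self):
        assert build_episodes(occ([0]), 7.0) == []

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 180), min_size=1, max_size=12, unique=True))
    def test_segmentation_matches_bruteforce(self, minutes):
        minutes = sorted(minutes)
        occurrences = occ(minutes)
        eps = build_episodes(occurrences, 7.0)
        times = [o.timestamp for o in occurrences]
        oracle_runs = [r for r in brute_force_episodes(times, 7.0) if len(r) >= 2]
        assert len(eps) == len(oracle_runs)
        for e, run in zip(eps, oracle_runs):
            assert e.start == times[run[0]] and e.end == times[run[-1]]
            gaps = sum(
                (times[j] - times[i]).total_seconds() / 60.0
                for i, j in zip(run, run[1:])
            )
            assert e.duration_min == pytest.approx(gaps)  # sum of gaps = end - start


# --- dedup, metrics, profile --------------------------------------------------


def srec(device, major, minor, when):
    return ScanRecord(when, device, "u", major, minor, -70)


def test_dedup_collapses_rebroadcasts_within_a_cycle():
    records = [
        srec("d", 1, 2, ts(1, 10, 0, 0)),
        srec("d", 1, 2, ts(1, 10, 0, 30)),  # 30 s later: same scan cycle
        srec("d", 1, 2, ts(1, 10, 5, 0)),
        srec("d2", 1, 2, ts(1, 10, 0, 30)),  # other device unaffected
    ]
    kept, collapsed = dedup_scans(records, window_min=1.0)
    assert collapsed == 1 and len(kept) == 3


def test_metrics_single_episode_fixture(roster, config):
    dyad = Dyad("F01-adolescent", "F01-mother", "mother")
    occurrences = [
        Occurrence(dyad, ts(1, 10, 0), "both"),
        Occurrence(dyad, ts(1, 10, 5), "both"),
        Occurrence(dyad, ts(1, 10, 10), "both"),
    ]
    eps = build_episodes(occurrences, config.gap_cutoff_min)
    table = compute_metrics(eps, occurrences, roster, config)
    row = table[(table["adolescent_id"] == "F01-adolescent") & (table["parent_role"] == "mother")].iloc[0]
    assert row["freq_total"] == 3
    assert row["freq_episodes"] == 1
    assert row["dur_total_min"] == 10.0
    assert row["freq_episodes"] <= row["freq_total"]


def test_metrics_weekday_weekend_denominators(roster, config):
    """14-day window starting Monday: 10 weekday and 4 weekend denominators."""
    dyad = Dyad("F01-adolescent", "F01-mother", "mother")
    occurrences = (
        occ([0, 5], dyad)  # Monday (day 1)
        + [Occurrence(dyad, ts(2, 10, 0), "both"), Occurrence(dyad, ts(2, 10, 5), "both")]
        + [Occurrence(dyad, ts(6, 12, 0), "both")]  # Saturday
    )
    table = compute_metrics([], occurrences, roster, config)
    row = table[(table["adolescent_id"] == "F01-adolescent") & (table["parent_role"] == "mother")].iloc[0]
    assert row["n_days"] == 14
    assert row["freq_weekday"] == pytest.approx(4 / 10)
    assert row["freq_weekend"] == pytest.approx(1 / 4)
    assert row["freq_per_day"] == pytest.approx(5 / 14)


def test_metrics_empty_dyad_flagged_not_dropped(roster, config):
    table = compute_metrics([], [], roster, config)
    assert len(table) == 3  # every roster dyad gets a row
    assert table["no_data"].all()
    assert (table["freq_total"] == 0).all() and (table["dur_total_min"] == 0).all()


def test_hourly_profile_conservation_and_binning(roster):
    dyad_m = Dyad("F01-adolescent", "F01-mother", "mother")
    dyad_f = Dyad("F01-adolescent", "F01-father", "father")
    occurrences = [
        Occurrence(dyad_m, ts(1, 16, 5), "both"),
        Occurrence(dyad_m, ts(1, 16, 55), "both"),
        Occurrence(dyad_f, ts(1, 19, 30), "both"),
    ]
    profile = hourly_profile(occurrences, roster)
    assert profile["total"].sum() == len(occurrences)
    monday_16 = profile[(profile["weekday"] == 0) & (profile["hour"] == 16)]
    assert monday_16["total"].sum() == 2
    assert set(profile["hour"]) == {16, 19}


def test_hourly_profile_per_family_disjoint_sums_to_pooled(roster):
    dyad1 = Dyad("F01-adolescent", "F01-mother", "mother")
    dyad2 = Dyad("F02-adolescent", "F02-mother", "mother")
    occurrences = [
        Occurrence(dyad1, ts(1, 10, 0), "both"),
        Occurrence(dyad1, ts(1, 10, 30), "both"),
        Occurrence(dyad2, ts(1, 15, 0), "both"),
    ]
    pooled = hourly_profile(occurrences, roster)
    per_fam = hourly_profile(occurrences, roster, per_family=True)
    assert set(per_fam["family_id"]) == {"F01", "F02"}
    hours_f1 = set(per_fam[per_fam["family_id"] == "F01"]["hour"])
    hours_f2 = set(per_fam[per_fam["family_id"] == "F02"]["hour"])
    assert hours_f1.isdisjoint(hours_f2)
    assert per_fam["total"].sum() == pooled["total"].sum() == 3
    # pooled mean per dyad divides by the two mother-dyads in the roster
    ten = pooled[(pooled["hour"] == 10) & (pooled["parent_role"] == "mother")]
    assert ten["mean_per_dyad"].iloc[0] == pytest.approx(1.0)


def test_window_then_merge_equals_merge_then_window_on_interior_fixture(roster, config):
    """When every member of a merged pair lies inside the window, the order of
    windowing and merging does not change the occurrence count."""
    records = []
    for i in range(4):
        records.append(srec("dev-F01-adolescent", 1, 2, ts(1, 12, 5 * i)))
        records.append(srec("dev-F01-mother", 1, 1, ts(1, 12, 5 * i, 40)))
    occ_then_window = apply_daytime_window(
        build_occurrences(records, roster, config)[0], config
    )
    windowed_records = apply_daytime_window(records, config)
    window_then_occ = build_occurrences(windowed_records, roster, config)[0]
    assert len(occ_then_window) == len(window_then_occ)
    assert [o.timestamp for o in occ_then_window] == [o.timestamp for o in window_then_occ]
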