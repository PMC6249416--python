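"""Sleep scoring: the >40-s immobility rule, bout segmentation, totals,
onsets and hourly profiles, checked against brute-force oracles."""

import numpy as np
import pytest

from circadia import (
    BoutList,
    ImmobilityTrace,
    LightSchedule,
    SleepSeries,
    bout_stats,
    hourly_profile,
    score_sleep,
    sleep_bouts,
    sleep_onset,
    sleep_totals,
)


def trace_from_runs(runs, baseline=0.3):
    """Build a 1-Hz trace from (duration_s, level) segments."""
    parts = [np.full(int(d), lvl) for d, lvl in runs]
    return ImmobilityTrace(samples=np.concatenate(parts), sample_period=1.0)


def oracle_sleep_seconds(samples, period, threshold=0.95, min_dur=40.0, strict=True):
    """Independent run-length scan: total qualifying immobile seconds."""
    total = 0.0
    run = 0
    for v in list(samples) + [-1.0]:
        if v >= threshold:
            run += 1
        else:
            dur = run * period
            if (dur > min_dur) if strict else (dur >= min_dur):
                total += dur
            run = 0
    return total


@pytest.mark.parametrize(
    "dur_s, level, expected_s",
    [
        (41, 1.0, 41.0),  # strictly exceeds 40 s
        (40, 1.0, 0.0),  # exactly 40 s does not qualify
        (120, 0.96, 120.0),  # threshold is >= 0.95
        (120, 0.94, 0.0),  # below the immobility threshold
    ],
)
def test_forty_second_rule(dur_s, level, expected_s):
    trace = trace_from_runs([(100, 0.0), (dur_s, level), (100, 0.0)])
    series = score_sleep(trace)
    assert series.bins.sum() * 60.0 == pytest.approx(expected_s, abs=1e-9)


def test_sliding_window_option_admits_exact_window():
    trace = trace_from_runs([(100, 0.0), (40, 1.0), (100, 0.0)])
    assert score_sleep(trace).bins.sum() == 0.0
    assert score_sleep(trace, method="sliding-window").bins.sum() * 60.0 == 40.0


def test_score_sleep_matches_run_length_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(50, 800))
        # mixture makes long immobile runs reasonably likely
        samples = np.where(rng.random(n) < 0.6, rng.uniform(0.95, 1.0, n),
                           rng.uniform(0.0, 0.95, n))
        period = float(rng.choice([1.0, 2.0, 5.0]))
        trace = ImmobilityTrace(samples=samples, sample_period=period)
        series = score_sleep(trace)
        expected = oracle_sleep_seconds(samples, period)
        assert series.bins.sum() * 60.0 == pytest.approx(expected, abs=1e-6)


def test_coarse_sampling_rejected():
    with pytest.raises(ValueError, match="sample period"):
        score_sleep(ImmobilityTrace(samples=np.ones(10), sample_period=120.0))


def test_minimum_duration_monotonicity(rng):
    samples = np.where(rng.random(2000) < 0.5, 1.0, 0.0)
    trace = ImmobilityTrace(samples=samples)
    totals = [
        score_sleep(trace, min_duration=d).bins.sum() for d in (10, 40, 80, 200)
    ]
    assert all(a >= b for a, b in zip(totals, totals[1:]))


# -- totals -----------------------------------------------------------------


def test_totals_day_night_partition(ld, rng):
    bins = rng.uniform(0, 1, 2880)  # two days
    series = SleepSeries(bins=bins, schedule=ld)
    t = sleep_totals(series)
    assert t["day_min"] + t["night_min"] == pytest.approx(t["total_min"])
    assert t["total_min"] == pytest.approx(bins.sum())


def test_totals_day_only_sleep(ld):
    bins = np.zeros(1440)
    bins[:720] = 1.0  # ZT0-12
    t = sleep_totals(SleepSeries(bins=bins, schedule=ld))
    assert t == {"day_min": 720.0, "night_min": 0.0, "total_min": 720.0}


def test_totals_all_zero(ld):
    t = sleep_totals(SleepSeries(bins=np.zeros(1440), schedule=ld))
    assert t["total_min"] == 0.0


# -- bouts ------------------------------------------------------------------


def series_with_blocks(blocks, n=1440, schedule=None):
    bins = np.zeros(n)
    for s, e in blocks:
        bins[s:e] = 1.0
    return SleepSeries(bins=bins, schedule=schedule or LightSchedule())


@pytest.mark.parametrize("gap, n_bouts", [(20, 1), (21, 2), (30, 2)])
def test_bout_gap_rule(gap, n_bouts):
    series = series_with_blocks([(100, 110), (110 + gap, 130 + gap)])
    assert len(sleep_bouts(series)) == n_bouts


def oracle_bouts(bins, gap_min):
    idx = [i for i, v in enumerate(bins) if v > 0]
    if not idx:
        return []
    groups = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] - 1 >= gap_min:
            groups.append([])
        groups[-1].append(i)
    return [(g[0], g[-1] + 1) for g in groups]


def test_bouts_match_gap_scan_oracle(rng):
    for _ in range(200):
        bins = (rng.random(500) < 0.05).astype(float)
        series = SleepSeries(bins=bins)
        got = [(int(s), int(e)) for s, e in sleep_bouts(series)]
        assert got == oracle_bouts(bins, 21)


# -- onset ------------------------------------------------------------------


def test_onset_examples():
    # bout at t = 12 h after 7 h bout-free time
    bouts = BoutList(bouts=[(300.0, 320.0), (720.0, 760.0)], kind="sleep")
    assert sleep_onset(bouts) == 720.0
    # every bout preceded by < 6 h of quiet
    bouts = BoutList(
        bouts=[(100.0, 110.0), (300.0, 320.0), (500.0, 520.0)], kind="sleep"
    )
    assert sleep_onset(bouts) is None
    assert sleep_onset(BoutList(bouts=[], kind="sleep")) is None


def test_onset_matches_exhaustive_scan(rng):
    for _ in range(200):
        starts = np.sort(rng.choice(np.arange(0, 2000, 10), size=8, replace=False))
        bouts = [(float(s), float(s) + 5.0) for s in starts]
        bl = BoutList(bouts=bouts, kind="sleep")
        got = sleep_onset(bl, min_inactivity=3.0)
        expected = None
        prev_end = 0.0
        for s, e in bouts:
            if s - prev_end >= 180.0 and expected is None:
                expected = s
            prev_end = e
        assert got == expected


# -- hourly profile ---------------------------------------------------------


def test_hourly_profile_flat_and_conserving(ld, rng):
    bins = np.tile(np.concatenate([np.ones(30), np.zeros(30)]), 48)  # 30 min/h, 2 d
    prof = hourly_profile(SleepSeries(bins=bins, schedule=ld))
    assert prof.shape == (24,)
    assert np.allclose(prof, 30.0)
    # conservation on random input
    bins = rng.uniform(0, 1, 2 * 1440)
    series = SleepSeries(bins=bins, schedule=ld)
    prof = hourly_profile(series)
    assert prof.sum() == pytest.approx(bins.sum() / 2.0)


def test_hourly_profile_of_repeated_day_equals_day(ld, rng):
    day = rng.uniform(0, 1, 1440)
    two = SleepSeries(bins=np.tile(day, 2), schedule=ld)
    one = SleepSeries(bins=day, schedule=ld)
    assert np.allclose(hourly_profile(two), hourly_profile(one))


# -- bout stats -------------------------------------------------------------


def test_bout_stats_phase_assignment(ld):
    series = series_with_blocks([(60, 85), (800, 810)], schedule=ld)
    # fractional final minute: 24 full + one half bin -> 24.5 min bout
    series.bins[84] = 0.5
    bouts = sleep_bouts(series)
    stats = bout_stats(series, bouts)
    assert stats["day_count"] == 1 and stats["night_count"] == 1
    assert stats["day_mean_duration_min"] == pytest.approx(24.5)
    assert stats["night_mean_duration_min"] == pytest.approx(10.0)
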