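"""Actigraphy metrics: bout segmentation, onsets, precision, alpha,
nocturnality, amount, phase angle, phase shifts and rolling peaks."""

from dataclasses import replace

import numpy as np
import pytest

from circadia import (
    ActivitySeries,
    ActivitySimConfig,
    LightSchedule,
    OnsetSequence,
    Regime,
    activity_amount,
    alpha,
    daily_onsets,
    detect_bouts,
    estimate_phase_shift,
    fragmentation,
    gen_activity,
    nocturnality,
    phase_angle,
    precision,
    rolling_peak,
)


def series_from_active(active_bins, bin_min=3.0, schedule=None):
    counts = np.where(np.asarray(active_bins, bool), 5, 0)
    return ActivitySeries(
        counts=counts, bin_min=bin_min, schedule=schedule or LightSchedule()
    )


@pytest.mark.parametrize("gap_bins, n_bouts", [(6, 1), (7, 2)])  # 18 vs 21 min
def test_bout_gap_rule_in_bins(gap_bins, n_bouts):
    active = np.zeros(200, bool)
    active[10:20] = True
    active[20 + gap_bins : 30 + gap_bins] = True
    assert len(detect_bouts(series_from_active(active))) == n_bouts


def test_detect_bouts_matches_brute_force(rng):
    for _ in range(200):
        counts = rng.poisson(0.3, size=400)
        series = ActivitySeries(counts=counts, bin_min=3.0)
        got = [(s, e) for s, e in detect_bouts(series)]
        # oracle: scan active bin indices, split at >= 21 min silence
        idx = [i for i, c in enumerate(counts) if c >= 1]
        expected = []
        if idx:
            groups = [[idx[0]]]
            for i in idx[1:]:
                if (i - groups[-1][-1] - 1) * 3.0 >= 21.0:
                    groups.append([])
                groups[-1].append(i)
            expected = [(g[0] * 3.0, (g[-1] + 1) * 3.0) for g in groups]
        assert got == expected


def test_fragmentation_is_bouts_per_day():
    active = np.zeros(4800, bool)  # 10 days of 3-min bins
    for d in range(10):
        active[d * 480 + 100 : d * 480 + 110] = True
    series = series_from_active(active)
    assert fragmentation(detect_bouts(series), 10) == 1.0


def test_daily_onsets_recover_generator_onsets(dd):
    cfg = ActivitySimConfig(
        tau=24.0, n_days=10, onset_phase=12.0, alpha_min=420.0,
        square_wave=True, nocturnality_target=None,
    )
    series = gen_activity(cfg, dd)
    ons = daily_onsets(series)
    assert len(ons) == 10
    assert np.allclose(ons.times, 720.0 + 1440.0 * np.arange(10))


def test_daily_onsets_recover_jittered_onsets_within_one_bin(dd):
    cfg = ActivitySimConfig(
        tau=24.0, n_days=10, onset_phase=12.0, alpha_min=420.0,
        onset_jitter_sd=5.0, square_wave=True, nocturnality_target=None, seed=7,
    )
    series = gen_activity(cfg, dd)
    ons = daily_onsets(series)
    rng = np.random.default_rng(7)
    true = 720.0 + 1440.0 * np.arange(10) + rng.normal(0, 5.0, 10)
    assert len(ons) == 10
    assert np.all(np.abs(ons.times - true) <= cfg.bin_min)


def test_precision_sign_and_closed_forms():
    # perfectly linear onsets
    lin = OnsetSequence(cycles=np.arange(8), times=700.0 + 1430.0 * np.arange(8))
    assert precision(lin) == pytest.approx(0.0, abs=1e-9)
    # residual pattern orthogonal to both intercept and slope -> exactly -10
    resid = np.tile([10.0, -10.0, -10.0, 10.0], 2)
    seq = OnsetSequence(cycles=np.arange(8), times=700.0 + 1440.0 * np.arange(8) + resid)
    assert precision(seq) == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        precision(OnsetSequence(cycles=[0, 1], times=[1.0, 2.0]))


def test_precision_tracks_half_normal_mean():
    # Gaussian onset jitter of sd sigma -> mean |residual| near sigma*sqrt(2/pi)
    sigma = 20.0
    rng = np.random.default_rng(11)
    mags = []
    for _ in range(200):
        times = 700.0 + 1440.0 * np.arange(10) + rng.normal(0, sigma, 10)
        mags.append(-precision(OnsetSequence(cycles=np.arange(10), times=np.sort(times))))
    expected = sigma * np.sqrt(2 / np.pi)
    assert np.mean(mags) == pytest.approx(expected, rel=0.15)


def test_alpha_recovers_active_phase(dd):
    cfg = ActivitySimConfig(
        tau=24.0, n_days=10, onset_phase=12.0, alpha_min=420.0,
        square_wave=True, nocturnality_target=None,
    )
    assert alpha(gen_activity(cfg, dd)) == pytest.approx(420.0)


def test_alpha_single_bout_day():
    active = np.zeros(480, bool)
    active[100:120] = True  # one 60-min bout
    assert alpha(series_from_active(active)) == pytest.approx(60.0)


def test_nocturnality_trivial_cases(ld):
    t = np.arange(480) * 3.0
    dark = ~ld.is_day(t)
    counts = np.where(dark, 10, 0)
    assert nocturnality(ActivitySeries(counts=counts, bin_min=3.0, schedule=ld)) == 100.0
    uniform = ActivitySeries(counts=np.full(480, 4), bin_min=3.0, schedule=ld)
    assert nocturnality(uniform) == pytest.approx(50.0)


def test_activity_amount():
    counts = np.zeros(4800)
    counts[::2] = 10  # 2400 counts/day over 10 days
    series = ActivitySeries(counts=counts, bin_min=3.0)
    assert activity_amount(series, n_days=10) == pytest.approx(100.0)
    assert activity_amount(ActivitySeries(counts=np.zeros(4800), bin_min=3.0)) == 0.0


def test_phase_angle(ld):
    ons = OnsetSequence(cycles=np.arange(5), times=720.0 + 1440.0 * np.arange(5))
    assert phase_angle(ons, ld) == pytest.approx(0.0)
    ons30 = OnsetSequence(cycles=np.arange(5), times=750.0 + 1440.0 * np.arange(5))
    assert phase_angle(ons30, ld) == pytest.approx(30.0)


def test_phase_shift_zero_and_imposed_delay():
    pre = OnsetSequence(cycles=np.arange(10), times=720.0 + 1428.0 * np.arange(10))
    same = OnsetSequence(
        cycles=np.arange(10, 20), times=720.0 + 1428.0 * np.arange(10, 20)
    )
    assert estimate_phase_shift(pre, same, 9) == pytest.approx(0.0, abs=1e-9)
    delayed = OnsetSequence(
        cycles=np.arange(10, 20), times=720.0 + 1428.0 * np.arange(10, 20) + 100.3
    )
    assert estimate_phase_shift(pre, delayed, 9) == pytest.approx(-100.3)


def test_phase_shift_matches_two_line_lstsq_oracle(rng):
    for _ in range(50):
        slope = 1440.0 + rng.normal(0, 5)
        shift = rng.normal(0, 60)
        c_pre, c_post = np.arange(10), np.arange(10, 20)
        t_pre = 500.0 + slope * c_pre + rng.normal(0, 10, 10)
        t_post = 500.0 + slope * c_post - shift + rng.normal(0, 10, 10)
        got = estimate_phase_shift(
            OnsetSequence(cycles=c_pre, times=np.sort(t_pre)),
            OnsetSequence(cycles=c_post, times=np.sort(t_post)),
            9,
        )
        # oracle: two independent normal-equation solves evaluated at cycle 10
        def line_at(c, t, x):
            A = np.vstack([c, np.ones_like(c, dtype=float)]).T
            beta, *_ = np.linalg.lstsq(A, t, rcond=None)
            return beta[0] * x + beta[1]

        expected = line_at(c_pre, np.sort(t_pre), 10) - line_at(
            c_post, np.sort(t_post), 10
        )
        assert got == pytest.approx(expected, abs=1e-8)


def test_phase_shift_generator_round_trip(dd):
    cfg = ActivitySimConfig(
        tau=24.0, n_days=20, onset_phase=12.0, alpha_min=420.0,
        square_wave=True, nocturnality_target=None,
        phase_shift_events=((9, -100.3),),
    )
    series = gen_activity(cfg, dd)
    ons = daily_onsets(series)
    pre = OnsetSequence(cycles=ons.cycles[:10], times=ons.times[:10])
    post = OnsetSequence(cycles=ons.cycles[10:], times=ons.times[10:])
    got = estimate_phase_shift(pre, post, 9)
    assert got == pytest.approx(-100.3, abs=cfg.bin_min)  # onsets are bin-quantised


def test_rolling_peak_cases(rng):
    t = np.arange(0, 12.0, 0.25)
    tri = np.maximum(0.0, 3.0 - np.abs(t - 6.0))
    assert abs(rolling_peak(t, tri) - 6.0) <= 0.5
    flat = np.ones_like(t)
    assert rolling_peak(t, flat) == 1.0  # first window's centre (tie rule)
    # random series vs exhaustive window oracle
    for _ in range(50):
        v = rng.random(t.size)
        best, centre = -np.inf, None
        t0 = 0.0
        while t0 + 2.0 <= t[-1] + 1e-12:
            sel = (t >= t0) & (t < t0 + 2.0)
            m = v[sel].mean()
            if m > best + 1e-12:
                best, centre = m, t0 + 1.0
            t0 += 1.0
        assert rolling_peak(t, v) == pytest.approx(centre)


def test_metrics_invariant_to_zero_padding_days(dd):
    cfg = ActivitySimConfig(
        tau=24.0, n_days=6, onset_phase=12.0, alpha_min=420.0,
        square_wave=True, nocturnality_target=None,
    )
    series = gen_activity(cfg, dd)
    padded = ActivitySeries(
        counts=np.concatenate([series.counts, np.zeros(480, int)]),
        bin_min=3.0, schedule=dd,
    )
    assert alpha(padded) == alpha(series)
    assert len(detect_bouts(padded)) == len(detect_bouts(series))
    onsets_a, onsets_b = daily_onsets(series), daily_onsets(padded)
    assert np.allclose(onsets_a.times, onsets_b.times)
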