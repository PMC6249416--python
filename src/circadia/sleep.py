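"""Immobility-defined sleep scoring and sleep metrics.

Behavioural sleep is inferred from video-tracking immobility: a maximal run
of samples whose body-immobility fraction is at least 95% counts as sleep
when it lasts strictly more than 40 s. Scored sleep seconds are accumulated
into 1-min bins, from which totals (day ZT0-12 / night ZT12-24), bouts
under a 21-min gap rule, bout onsets and hourly profiles are derived.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np

from .core import BoutList, ImmobilityTrace, LightSchedule, SleepSeries

logger = logging.getLogger(__name__)

__all__ = [
    "score_sleep",
    "sleep_totals",
    "sleep_bouts",
    "sleep_onset",
    "hourly_profile",
    "bout_stats",
]


def _immobile_runs(mask: np.ndarray):
    """Yield (start_idx, stop_idx) of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def score_sleep(
    trace: ImmobilityTrace,
    immobility_threshold: float = 0.95,
    min_duration: float = 40.0,
    schedule: Optional[LightSchedule] = None,
    method: str = "maximal-run",
) -> SleepSeries:
    """Score behavioural sleep from an immobility trace.

    A maximal run of samples with immobility >= ``immobility_threshold``
    is sleep iff its duration strictly exceeds ``min_duration`` seconds
    (the default 40-s rule).  Qualifying seconds are accumulated into 1-min
    bins, each run contributing its overlap with each half-open minute.

    Parameters
    ----------
    method
        ``"maximal-run"`` (default): strict ``> min_duration`` on maximal
        immobile runs.  ``"sliding-window"``: a sample is asleep if it is
        covered by any fully-immobile window of length ``min_duration``,
        i.e. runs qualify at ``>= min_duration``.
    """
    if trace.sample_period > 60.0:
        raise ValueError(
            "sample period exceeds 60 s; the 40-s sleep rule cannot be resolved"
        )
    if method not in ("maximal-run", "sliding-window"):
        raise ValueError(f"unknown scoring method {method!r}")

    sp = trace.sample_period
    mask = trace.samples >= immobility_threshold
    n_sec = trace.samples.size * sp
    n_bins = max(1, math.ceil(n_sec / 60.0)) if trace.samples.size else 0
    bins = np.zeros(n_bins)

    for i0, i1 in _immobile_runs(mask):
        dur = (i1 - i0) * sp
        ok = dur > min_duration if method == "maximal-run" else dur >= min_duration
        if not ok:
            continue
        t0, t1 = i0 * sp, i1 * sp  # seconds since trace start
        b0, b1 = int(t0 // 60), int(math.ceil(t1 / 60.0))
        for b in range(b0, min(b1, n_bins)):
            lo, hi = b * 60.0, (b + 1) * 60.0
            bins[b] += (min(t1, hi) - max(t0, lo)) / 60.0
    return SleepSeries(
        bins=bins,
        schedule=schedule if schedule is not None else LightSchedule(),
        start_time=trace.start_time,
    )


def sleep_totals(series: SleepSeries) -> dict:
    """Total sleep minutes over the record, split into day (ZT0-12) and night.

    The split follows the attached light schedule; under DD the projected
    ZT from the prior entrained phase is used (a debug message notes this).
    """
    sched = series.schedule
    if sched.regime.value != "LD":
        logger.debug("day/night split uses projected ZT under %s", sched.regime.value)
    day_mask = sched.is_day(series.times)
    day = float(series.bins[day_mask].sum())
    night = float(series.bins[~day_mask].sum())
    return {"day_min": day, "night_min": night, "total_min": day + night}


def sleep_bouts(series: SleepSeries, gap_min: float = 21.0) -> BoutList:
    """Segment a sleep series into bouts under the minimum-gap rule.

    Consecutive sleep-containing minutes whose separating sleep-free gap is
    shorter than ``gap_min`` belong to one bout; a gap of ``gap_min`` or
    more splits bouts.
    """
    idx = np.flatnonzero(series.bins > 0)
    if idx.size == 0:
        return BoutList(bouts=[], kind="sleep")
    bouts = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 >= gap_min:  # empty minutes between sleep bins
            bouts.append((series.start_time + start, series.start_time + prev + 1.0))
            start = i
        prev = i
    bouts.append((series.start_time + start, series.start_time + prev + 1.0))
    return BoutList(bouts=bouts, kind="sleep")


def sleep_onset(
    bouts: BoutList, min_inactivity: float = 6.0, record_start: float = 0.0
):
    """Start time (min) of the first bout preceded by >= ``min_inactivity``
    hours without a bout of the same kind; ``None`` if no bout qualifies.

    For the first bout the preceding bout-free interval is measured from
    ``record_start``.
    """
    gap_req = min_inactivity * 60.0
    prev_end = record_start
    for s, e in bouts:
        if s - prev_end >= gap_req:
            return float(s)
        prev_end = e
    return None


def hourly_profile(series: SleepSeries) -> np.ndarray:
    """Mean sleep minutes per hour-of-day (ZT0..ZT23) across complete days.

    An incomplete final day is dropped (logged).  The returned 24 values
    satisfy ``profile.sum() == total_sleep / n_days``.
    """
    n_days = len(series.bins) // 1440
    if n_days < 1:
        raise ValueError("at least one complete day is required")
    if len(series.bins) % 1440:
        logger.warning(
            "dropping incomplete final day (%d leftover minutes)",
            len(series.bins) % 1440,
        )
    data = series.bins[: n_days * 1440].reshape(n_days, 24, 60)
    # shift so index 0 is ZT0
    offset_h = series.schedule.zt_hours(series.start_time)
    hourly = data.sum(axis=2).mean(axis=0)
    shift = int(round(offset_h)) % 24
    return np.roll(hourly, shift)


def bout_stats(series: SleepSeries, bouts: BoutList) -> dict:
    """Per-phase (day ZT0-12 / night) bout counts and mean bout durations.

    A bout's phase is assigned from its start time; a sleep bout's duration
    is the summed sleep minutes it contains (so partial minutes count
    fractionally), matching minute-binned exports.
    """
    day_durs, night_durs = [], []
    t = series.times
    for s, e in bouts:
        sel = (t >= s) & (t < e)
        dur = float(series.bins[sel].sum())
        if bool(series.schedule.is_day(s)):
            day_durs.append(dur)
        else:
            night_durs.append(dur)
    return {
        "day_count": len(day_durs),
        "night_count": len(night_durs),
        "day_mean_duration_min": float(np.mean(day_durs)) if day_durs else float("nan"),
        "night_mean_duration_min": float(np.mean(night_durs)) if night_durs else float("nan"),
    }
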