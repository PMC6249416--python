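"""Locomotor activity-rhythm metrics from binned wheel-running counts.

Implements the standard actigraphy panel: activity bouts under a 21-min
gap rule, fragmentation (bouts/day), per-cycle activity onsets, onset
precision about a regression line, alpha (active-phase length),
nocturnality, activity amount, phase angle of entrainment, phase-shift
estimation from pre/post onset regression lines, and a rolling
time-of-peak for windowed firing-rate-style profiles.

Sign conventions
----------------
* precision is reported as the *negated* mean absolute onset residual, so
  larger magnitudes mean worse precision and printed values are negative;
* phase shifts are phase differences: a *delayed* onset (later clock time)
  is a negative shift, an advance positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ActivitySeries, BoutList, LightSchedule

__all__ = [
    "OnsetSequence",
    "detect_bouts",
    "fragmentation",
    "daily_onsets",
    "precision",
    "alpha",
    "nocturnality",
    "activity_amount",
    "phase_angle",
    "estimate_phase_shift",
    "rolling_peak",
    "plot_actogram",
]


@dataclass
class OnsetSequence:
    """Per-cycle activity (or sleep) onset times.

    ``cycles`` are integer cycle indices (gaps allowed where no onset
    qualified); ``times`` are onset times in minutes, strictly increasing.
    """

    cycles: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.cycles.size != self.times.size:
            raise ValueError("cycles and times must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("onset times must be strictly increasing")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("at most one onset per cycle")

    def __len__(self) -> int:
        return len(self.times)


def detect_bouts(
    series: ActivitySeries, gap_min: float = 21.0, active_threshold: float = 1.0
) -> BoutList:
    """Segment supra-threshold activity into bouts (21-min gap rule).

    Bins with ``counts >= active_threshold`` are active; active stretches
    separated by silent gaps shorter than ``gap_min`` merge into one bout,
    a silent gap of ``gap_min`` minutes or more splits bouts.
    """
    idx = np.flatnonzero(series.counts >= active_threshold)
    if idx.size == 0:
        return BoutList(bouts=[], kind="activity")
    w = series.bin_min
    bouts = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if (i - prev - 1) * w >= gap_min:
            bouts.append(
                (series.start_time + start * w, series.start_time + (prev + 1) * w)
            )
            start = i
        prev = i
    bouts.append((series.start_time + start * w, series.start_time + (prev + 1) * w))
    return BoutList(bouts=bouts, kind="activity")


def fragmentation(bouts: BoutList, n_days: float) -> float:
    """Number of bouts per day."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    return len(bouts) / n_days


def daily_onsets(
    series: ActivitySeries,
    min_inactivity: float = 6.0,
    cycle_h: float = 24.0,
    gap_min: float = 21.0,
    active_threshold: float = 1.0,
) -> OnsetSequence:
    """Per-cycle onsets: the first bout after >= ``min_inactivity`` hours
    without a bout.

    ``cycle_h`` is the cycle length used to index onsets (24 h in LD; in
    DD pass the running period estimate so drifting onsets stay within
    their cycles).  Cycles without a qualifying bout are simply absent
    from the sequence.
    """
    bouts = detect_bouts(series, gap_min=gap_min, active_threshold=active_threshold)
    gap_req = min_inactivity * 60.0
    cyc_len = cycle_h * 60.0
    cycles, times = [], []
    prev_end = series.start_time
    for s, e in bouts:
        if s - prev_end >= gap_req:
            c = int((s - series.start_time) // cyc_len)
            if not cycles or c > cycles[-1]:
                cycles.append(c)
                times.append(float(s))
        prev_end = e
    return OnsetSequence(cycles=np.array(cycles), times=np.array(times))


def _fit_line(cycles: np.ndarray, times: np.ndarray):
    """Least-squares line times ~ cycles; returns (slope, intercept)."""
    slope, intercept = np.polyfit(np.asarray(cycles, float), np.asarray(times, float), 1)
    return slope, intercept


def precision(onsets: OnsetSequence) -> float:
    """Onset precision: negated mean |residual| about a best-fit line (min).

    Requires at least 3 onsets.  Perfectly linear onsets give 0; noisier
    onsets give more negative values (paper-style sign convention).
    """
    if len(onsets) < 3:
        raise ValueError("precision requires at least 3 onsets")
    slope, intercept = _fit_line(onsets.cycles, onsets.times)
    resid = onsets.times - (slope * onsets.cycles + intercept)
    return -float(np.mean(np.abs(resid)))


def alpha(
    series: ActivitySeries,
    min_inactivity: float = 6.0,
    gap_min: float = 21.0,
    active_threshold: float = 1.0,
) -> float:
    """Mean length of the daily active phase (onset to offset, minutes).

    Bouts are grouped into daily episodes separated by >= ``min_inactivity``
    hours of bout-free time; each episode contributes
    ``offset - onset`` where the offset is the end of its last bout.
    """
    bouts = detect_bouts(series, gap_min=gap_min, active_threshold=active_threshold)
    if len(bouts) == 0:
        return float("nan")
    gap_req = min_inactivity * 60.0
    spans = []
    ep_start, ep_end = bouts.bouts[0]
    for s, e in bouts.bouts[1:]:
        if s - ep_end >= gap_req:
            spans.append(ep_end - ep_start)
            ep_start = s
        ep_end = e
    spans.append(ep_end - ep_start)
    return float(np.mean(spans))


def nocturnality(series: ActivitySeries) -> float:
    """Percent of total activity occurring in the dark phase."""
    total = series.counts.sum()
    if total == 0:
        return float("nan")
    dark = series.counts[series.schedule.is_dark(series.times)].sum()
    return 100.0 * float(dark) / float(total)


def activity_amount(series: ActivitySeries, n_days: float | None = None) -> float:
    """Mean activity in counts (revolutions) per hour over ``n_days``."""
    if n_days is None:
        n_days = series.n_days
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    return float(series.counts.sum()) / (24.0 * n_days)


def phase_angle(onsets: OnsetSequence, schedule: LightSchedule) -> float:
    """Mean offset of onsets from lights-off (min); negative = onset early."""
    if len(onsets) == 0:
        raise ValueError("no onsets")
    offs = np.array([schedule.lights_off_min(int(c)) for c in onsets.cycles])
    return float(np.mean(onsets.times - offs))


def estimate_phase_shift(
    onsets_pre: OnsetSequence, onsets_post: OnsetSequence, event_cycle: int
) -> float:
    """Phase shift (min) between pre- and post-event onset regression lines.

    One least-squares line is fitted per side (time ~ cycle, using absolute
    cycle indices); the shift is the phase difference ``pre - post``
    evaluated at the first cycle after the event, so onsets occurring
    *later* than the pre-event line predicts give a negative value
    (phase delay), matching the convention of printing delays negative.
    """
    if len(onsets_pre) < 3 or len(onsets_post) < 3:
        raise ValueError("phase-shift estimation requires >= 3 onsets per side")
    s0, i0 = _fit_line(onsets_pre.cycles, onsets_pre.times)
    s1, i1 = _fit_line(onsets_post.cycles, onsets_post.times)
    c = event_cycle + 1
    return float((s0 * c + i0) - (s1 * c + i1))


def rolling_peak(
    times_h: np.ndarray, values: np.ndarray, window_h: float = 2.0, lag_h: float = 1.0
) -> float:
    """Centre time (h) of the maximal-mean window (width ``window_h``,
    stepped every ``lag_h``); ties resolve to the earliest window.

    The classic use is locating the time-of-peak of a firing-rate profile
    from means over sequential 2-h periods with 1-h lags.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size == 0:
        raise ValueError("times and values must be equal-length and non-empty")
    best_mean, best_centre = -np.inf, None
    t0 = t[0]
    while t0 + window_h <= t[-1] + 1e-12:
        sel = (t >= t0 - 1e-12) & (t < t0 + window_h - 1e-12)
        if sel.any():
            m = v[sel].mean()
            if m > best_mean + 1e-12:
                best_mean, best_centre = m, t0 + window_h / 2.0
        t0 += lag_h
    if best_centre is None:
        raise ValueError("no window fits the series")
    return float(best_centre)


def plot_actogram(
    series: ActivitySeries,
    out_path=None,
    double_plot: bool = True,
    normalise_frac: float = 0.85,
    ax=None,
):
    """Double-plotted actogram: one row per day (two consecutive days per
    row when ``double_plot``), bars normalised to ``normalise_frac`` of the
    series maximum (the conventional 85%-of-max display scale)."""
    import matplotlib

    if out_path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    per_day = int(round(1440.0 / series.bin_min))
    n_days = series.n_bins // per_day
    if n_days < 1:
        raise ValueError("need at least one full day to plot")
    data = series.counts[: n_days * per_day].reshape(n_days, per_day).astype(float)
    scale = normalise_frac * data.max() if data.max() > 0 else 1.0
    data = np.clip(data / scale, 0, 1)

    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 0.4 * n_days + 1))
    else:
        fig = ax.figure
    width_h = 48.0 if double_plot else 24.0
    hours = np.arange(per_day) * series.bin_min / 60.0
    for d in range(n_days):
        row = data[d]
        ax.vlines(hours, d, d + row * 0.9, lw=0.5, color="k")
        if double_plot and d + 1 < n_days:
            ax.vlines(24.0 + hours, d, d + data[d + 1] * 0.9, lw=0.5, color="k")
    ax.set_xlim(0, width_h)
    ax.set_ylim(n_days, 0)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("day")
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return ax
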