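"""Shared domain containers for behavioural chronobiology records.

Conventions used throughout the package:

* all times are stored in **minutes since recording start** unless a name
  says otherwise;
* Zeitgeber time (ZT) is measured in hours, ZT0 = lights-on; under a 12:12
  light-dark (LD) cycle ZT12 is lights-off;
* bins are half-open intervals ``[t, t + width)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Regime",
    "LightSchedule",
    "ActivitySeries",
    "ImmobilityTrace",
    "SleepSeries",
    "Bout",
    "BoutList",
]


class Regime(str, enum.Enum):
    """Lighting regime: entrained LD, constant darkness, constant light."""

    LD = "LD"
    DD = "DD"
    LL = "LL"


@dataclass(frozen=True)
class LightSchedule:
    """Imposed lighting schedule.

    Parameters
    ----------
    regime
        ``LD`` (light-dark cycle), ``DD`` (constant darkness) or ``LL``
        (constant light).
    lights_on
        Clock time of lights-on in hours relative to recording start; by
        convention recording start coincides with ZT0, so the default is 0.
    photoperiod
        Hours of light per 24-h cycle (12 for a 12:12 cycle). Under DD/LL
        the photoperiod defines the *projected* day/night split carried
        over from the prior entrained phase.
    pulse_events
        Discrete light manipulations as ``(time_min, duration_min, label)``
        tuples, strictly increasing in time.
    """

    regime: Regime = Regime.LD
    lights_on: float = 0.0
    photoperiod: float = 12.0
    pulse_events: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod <= 24.0:
            raise ValueError(f"photoperiod must be in [0, 24] h, got {self.photoperiod}")
        times = [e[0] for e in self.pulse_events]
        if any(e[1] <= 0 for e in self.pulse_events):
            raise ValueError("pulse durations must be > 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("pulse events must be strictly increasing in time")
        if isinstance(self.regime, str) and not isinstance(self.regime, Regime):
            object.__setattr__(self, "regime", Regime(self.regime))

    def zt_hours(self, time_min) -> np.ndarray:
        """Zeitgeber time (hours in [0, 24)) of absolute times in minutes."""
        return (np.asarray(time_min, dtype=float) / 60.0 - self.lights_on) % 24.0

    def is_day(self, time_min) -> np.ndarray:
        """True where a time falls in the (projected) light phase ZT0-photoperiod."""
        return self.zt_hours(time_min) < self.photoperiod

    def is_dark(self, time_min) -> np.ndarray:
        """True where the lights are actually off (LL has no dark phase)."""
        if self.regime is Regime.LL:
            return np.zeros(np.shape(np.asarray(time_min)), dtype=bool)
        if self.regime is Regime.DD:
            return np.ones(np.shape(np.asarray(time_min)), dtype=bool)
        return ~self.is_day(time_min)

    def lights_off_min(self, cycle: int) -> float:
        """Absolute time (min) of lights-off in cycle ``cycle`` (0-based)."""
        return (self.lights_on + self.photoperiod) * 60.0 + cycle * 1440.0


@dataclass
class ActivitySeries:
    """Uniformly binned locomotor activity counts (e.g. wheel revolutions)."""

    counts: np.ndarray
    bin_min: float = 3.0
    start_time: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_min <= 0:
            raise ValueError("bin width must be positive")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Bin start times in minutes."""
        return self.start_time + np.arange(self.n_bins) * self.bin_min

    @property
    def duration_min(self) -> float:
        return self.n_bins * self.bin_min

    @property
    def n_days(self) -> float:
        return self.duration_min / 1440.0


@dataclass
class ImmobilityTrace:
    """Per-sample fraction of the body that is immobile, in [0, 1]."""

    samples: np.ndarray
    sample_period: float = 1.0  # seconds
    start_time: float = 0.0  # minutes

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_period <= 0:
            raise ValueError("sample period must be positive")
        if self.samples.size and (self.samples.min() < 0 or self.samples.max() > 1):
            raise ValueError("immobility fractions must lie in [0, 1]")


@dataclass
class SleepSeries:
    """Sleep minutes per 1-min bin (each value in [0, 1])."""

    bins: np.ndarray
    schedule: LightSchedule = field(default_factory=LightSchedule)
    start_time: float = 0.0  # minutes

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.size and (self.bins.min() < -1e-9 or self.bins.max() > 1 + 1e-9):
            raise ValueError("per-minute sleep values must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.bins), dtype=float)


Bout = tuple  # (start_min, end_min)


@dataclass
class BoutList:
    """Sorted, non-overlapping bouts of one kind ('sleep' or 'activity')."""

    bouts: list
    kind: str = "activity"

    def __post_init__(self) -> None:
        if self.kind not in ("sleep", "activity"):
            raise ValueError("kind must be 'sleep' or 'activity'")
        for (s, e) in self.bouts:
            if e <= s:
                raise ValueError(f"bout end must exceed start, got ({s}, {e})")
        for (_, e0), (s1, _) in zip(self.bouts, self.bouts[1:]):
            if s1 < e0:
                raise ValueError("bouts must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)

    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.bouts], dtype=float)

    def ends(self) -> np.ndarray:
        return np.array([e for _, e in self.bouts], dtype=float)
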