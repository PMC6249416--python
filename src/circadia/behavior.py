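"""Behavioural test quantification: novel-object discrimination, zone
occupancy with body-fraction hysteresis, occupancy heat maps, and the
trivial densitometry band normalisation.

Zone entries follow the tracking-software convention: an animal enters a
zone when >= 85% of its body is inside and exits when >= 75% of its body
is outside (in-fraction <= 25%), i.e. an asymmetric hysteresis band over
the per-frame body-in-zone fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZoneTrack",
    "ObjectTimes",
    "discrimination_index",
    "zone_occupancy",
    "occupancy_heatmap",
    "normalize_band",
]


@dataclass
class ZoneTrack:
    """Per-frame body-in-zone fraction for one or more named zones.

    ``fractions`` maps zone name to an array of values in [0, 1], all of
    one length; ``positions`` (optional) are per-frame (x, y) coordinates
    in metres used for per-zone distance.
    """

    fractions: dict
    frame_rate: float = 30.0
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        lengths = set()
        for name, arr in self.fractions.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"zone {name!r}: fractions must lie in [0, 1]")
            self.fractions[name] = arr
            lengths.add(arr.size)
        if len(lengths) > 1:
            raise ValueError("all zones must share one frame count")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)


@dataclass(frozen=True)
class ObjectTimes:
    """Exploration times (s) for novel and familiar objects."""

    t_novel: float
    t_familiar: float

    def __post_init__(self) -> None:
        if self.t_novel < 0 or self.t_familiar < 0:
            raise ValueError("exploration times must be non-negative")


def discrimination_index(times: ObjectTimes) -> float:
    """Discrimination index DI = t_novel / (t_novel + t_familiar).

    0.5 means no preference; 1.0 means only the novel object was
    explored.  Raises when both times are zero (DI undefined; no
    minimum-exploration criterion is imposed upstream).
    """
    total = times.t_novel + times.t_familiar
    if total <= 0:
        raise ValueError("DI undefined: no object exploration time")
    return times.t_novel / total


def _hysteresis_states(frac: np.ndarray, enter: float, exit_in: float):
    """Per-frame IN/OUT states and entry count for one zone."""
    state = bool(frac[0] >= enter) if frac.size else False
    states = np.empty(frac.size, dtype=bool)
    entries = 0
    for i, f in enumerate(frac):
        if not state and f >= enter:
            state = True
            entries += 1
        elif state and f <= exit_in:
            state = False
        states[i] = state
    return states, entries


def zone_occupancy(
    track: ZoneTrack, enter_frac: float = 0.85, exit_out_frac: float = 0.75
) -> dict:
    """Entries, occupancy time and distance per zone via hysteresis.

    OUT->IN when the in-fraction reaches ``enter_frac``; IN->OUT when the
    out-fraction reaches ``exit_out_frac`` (in-fraction <=
    ``1 - exit_out_frac``).  The initial state at frame 0 is IN when the
    fraction already exceeds the entry threshold, and is not counted as
    an entry.  Distance is summed over frames spent IN (requires
    ``track.positions``).
    """
    exit_in = 1.0 - exit_out_frac
    if exit_in >= enter_frac:
        raise ValueError("hysteresis band is empty: need 1 - exit_out_frac < enter_frac")
    out = {}
    step = None
    if track.positions is not None and len(track.positions) > 1:
        step = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    for name, frac in track.fractions.items():
        if frac.size == 0:
            out[name] = {"entries": 0, "time_s": 0.0, "distance_m": 0.0}
            continue
        states, entries = _hysteresis_states(frac, enter_frac, exit_in)
        time_s = float(states.sum()) / track.frame_rate
        dist = float(step[states[1:]].sum()) if step is not None else 0.0
        out[name] = {"entries": entries, "time_s": time_s, "distance_m": dist}
    return out


def occupancy_heatmap(
    positions_by_animal,
    grid,
    extent=None,
    group_normalise: bool = True,
):
    """Relative dwell-time heat maps for a comparison group of animals.

    Parameters
    ----------
    positions_by_animal
        List of per-frame (x, y) coordinate arrays, one per animal.
    grid
        (nx, ny) number of cells.
    extent
        ((xmin, xmax), (ymin, ymax)); defaults to the joint data range.
    group_normalise
        Normalise every map to the *comparative maximum* across the
        whole group (heat maps are then only comparable within the
        group, values in [0, 1]).  With ``False``, each map holds raw
        frame counts.
    """
    arrays = [np.asarray(p, dtype=float) for p in positions_by_animal]
    if not arrays:
        raise ValueError("need at least one animal")
    allpos = np.vstack(arrays)
    if extent is None:
        extent = (
            (allpos[:, 0].min(), allpos[:, 0].max()),
            (allpos[:, 1].min(), allpos[:, 1].max()),
        )
    maps = [
        np.histogram2d(p[:, 0], p[:, 1], bins=grid, range=extent)[0] for p in arrays
    ]
    if group_normalise:
        peak = max(m.max() for m in maps)
        if peak > 0:
            maps = [m / peak for m in maps]
    return maps


def normalize_band(raw: float, background: float, reference: float) -> float:
    """Background-corrected band intensity normalised to a loading
    reference (e.g. beta-actin): ``(raw - background) / reference``."""
    if reference <= 0:
        raise ValueError("reference intensity must be positive")
    return (raw - background) / reference
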