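"""Readers, writers and the pipeline runner.

File conventions: times are serialised in minutes, ZT0 = lights-on, bins
are half-open ``[t, t + width)``.  Every file written by the package
carries a provenance header (tool version, config hash, seed) as ``#``
comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .core import ActivitySeries, ImmobilityTrace, LightSchedule, Regime, SleepSeries
from .morphometry import NeuronTrace

logger = logging.getLogger(__name__)

__all__ = [
    "read_activity_csv",
    "write_activity_csv",
    "read_immobility_csv",
    "write_immobility_csv",
    "write_sleep_csv",
    "read_sleep_csv",
    "read_swc",
    "write_swc",
    "schedule_from_string",
    "run_pipeline",
]


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance(extra: dict | None = None) -> list:
    lines = [
        f"# circadia v{__version__}",
        "# times=minutes zt_convention=ZT0-lights-on bins=half-open",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def schedule_from_string(text: str) -> LightSchedule:
    """Parse a schedule string: ``LD12:12``, ``LD``, ``DD`` or ``LL``."""
    text = text.strip()
    if text.startswith("LD"):
        photo = 12.0
        if ":" in text:
            photo = float(text[2:].split(":")[0])
        return LightSchedule(regime=Regime.LD, photoperiod=photo)
    if text in ("DD", "LL"):
        return LightSchedule(regime=Regime(text))
    raise ValueError(f"unknown schedule {text!r}")


# ---------------------------------------------------------------------------
# activity / immobility / sleep tables
# ---------------------------------------------------------------------------

def _read_table(path, n_cols: int = 2):
    """Two-column numeric table reader that reports bad lines."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            if rows == [] and not _is_number(parts[0]):
                # header line
                continue
            if len(parts) < n_cols or not all(_is_number(p) for p in parts[:n_cols]):
                raise ValueError(f"{path}: malformed row at line {lineno}: {s!r}")
            rows.append([float(p) for p in parts[:n_cols]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_activity_csv(
    path, dialect: str = "csv", schedule: LightSchedule | None = None
) -> ActivitySeries:
    """Read binned activity counts.

    ``csv`` dialect: header ``time_min,count`` then one row per bin.
    ``awd`` dialect (Actiwatch-AWD-like): 7 header lines (subject id,
    start date, start time, bin length in minutes, then three unused
    metadata lines) followed by one count per line.
    """
    schedule = schedule or LightSchedule()
    if dialect == "awd":
        with open(path) as fh:
            lines = [l.rstrip("\n") for l in fh]
        if len(lines) < 8:
            raise ValueError(f"{path}: truncated AWD file")
        bin_min = float(lines[3])
        counts = []
        for lineno, s in enumerate(lines[7:], start=8):
            s = s.strip()
            if not s:
                continue
            if not _is_number(s):
                raise ValueError(f"{path}: malformed count at line {lineno}: {s!r}")
            counts.append(float(s))
        return ActivitySeries(
            counts=np.asarray(counts), bin_min=bin_min, schedule=schedule
        )
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    data = _read_table(path)
    times, counts = data[:, 0], data[:, 1]
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts")
    steps = np.diff(times)
    if steps.size and not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: non-uniform bins")
    bin_min = float(steps[0]) if steps.size else 3.0
    return ActivitySeries(
        counts=counts, bin_min=bin_min, start_time=float(times[0]), schedule=schedule
    )


def write_activity_csv(series: ActivitySeries, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance(meta)) + "\n")
        fh.write("time_min,count\n")
        for t, c in zip(series.times, series.counts):
            fh.write(f"{t:.6g},{c:g}\n")


def read_immobility_csv(path) -> ImmobilityTrace:
    """Columns ``time_min,value`` with one row per sample."""
    data = _read_table(path)
    times, values = data[:, 0], data[:, 1]
    steps = np.diff(times)
    if steps.size and not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: non-uniform sampling")
    period_s = float(steps[0]) * 60.0 if steps.size else 1.0
    return ImmobilityTrace(
        samples=values, sample_period=period_s, start_time=float(times[0])
    )


def write_immobility_csv(trace: ImmobilityTrace, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance(meta)) + "\n")
        fh.write("time_min,value\n")
        for i, v in enumerate(trace.samples):
            t = trace.start_time + i * trace.sample_period / 60.0
            fh.write(f"{t:.8g},{v:.6g}\n")


def write_sleep_csv(series: SleepSeries, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance(meta)) + "\n")
        fh.write("time_min,sleep_min\n")
        for t, v in zip(series.times, series.bins):
            fh.write(f"{t:.6g},{v:.6g}\n")


def read_sleep_csv(path, schedule: LightSchedule | None = None) -> SleepSeries:
    data = _read_table(path)
    return SleepSeries(
        bins=data[:, 1],
        schedule=schedule or LightSchedule(),
        start_time=float(data[0, 0]),
    )


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path) -> NeuronTrace:
    """Read a standard 7-column SWC reconstruction.

    Columns: id, type, x, y, z, radius, parent (parent -1 for the root).
    The analysis is 2-D (camera-lucida projections); a non-zero z column
    is ignored with a warning.  Orphan nodes and cycles raise.
    """
    nodes, parents = {}, {}
    has_z = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 SWC columns")
            nid, _typ = int(parts[0]), int(parts[1])
            x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            parent = int(parts[6])
            if abs(z) > 1e-9:
                has_z = True
            nodes[nid] = (x, y)
            parents[nid] = parent
    if has_z:
        warnings.warn("SWC has non-zero z coordinates; analysis is 2-D, z ignored")
    for nid, p in parents.items():
        if p != -1 and p not in nodes:
            raise ValueError(f"{path}: node {nid} references missing parent {p}")
    return NeuronTrace(nodes=nodes, parents=parents)


def write_swc(trace: NeuronTrace, path, radius: float = 1.0) -> None:
    with open(path, "w") as fh:
        for line in _provenance():
            fh.write(line + "\n")
        for nid in sorted(trace.nodes):
            x, y = trace.nodes[nid]
            p = trace.parents[nid]
            typ = 1 if p == -1 else 3  # soma / basal dendrite
            fh.write(f"{nid} {typ} {x:.4f} {y:.4f} 0.0 {radius:.3f} {p}\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("simulate_activity", "activity_metrics", "periodogram",
                 "simulate_sleep", "sleep_metrics")


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the requested analysis stages and write results.

    ``config`` mirrors the simulator/metric parameter types, with a
    ``stages`` list naming what to run.  Outputs (CSV series, a
    ``metrics.json``, and ``run.log`` capturing version/seed/parameters)
    go to ``out_dir``.  Fully deterministic given (config, seed).
    """
    from dataclasses import replace

    from . import actigraphy as act
    from . import periodogram as pg
    from . import sleep as slp
    from . import synthetic as syn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    for st in stages:
        if st not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {st!r}; known: {_KNOWN_STAGES}")
    chash = _config_hash(config)
    meta = {"config_hash": chash, "seed": seed}
    metrics: dict = {"config_hash": chash, "seed": seed, "version": __version__}
    schedule = schedule_from_string(config.get("schedule", "LD12:12"))

    series = None
    sleep_series = None
    if "simulate_activity" in stages:
        cfg = syn.ActivitySimConfig(**config.get("activity", {}))
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        series = syn.gen_activity(cfg, schedule)
        write_activity_csv(series, out_dir / "activity.csv", meta)
    elif "activity_metrics" in stages or "periodogram" in stages:
        series = read_activity_csv(config["activity_csv"], schedule=schedule)

    if "activity_metrics" in stages:
        bouts = act.detect_bouts(series)
        onsets = act.daily_onsets(series)
        m = {
            "fragmentation_bouts_per_day": act.fragmentation(bouts, series.n_days),
            "amount_rev_per_h": act.activity_amount(series),
            "nocturnality_pct": act.nocturnality(series),
            "alpha_min": act.alpha(series),
        }
        if len(onsets) >= 3:
            m["precision_min"] = act.precision(onsets)
            if schedule.regime is Regime.LD:
                m["phase_angle_min"] = act.phase_angle(onsets, schedule)
        metrics["activity"] = m

    if "periodogram" in stages:
        p = pg.chi2_periodogram(series, **config.get("periodogram", {}))
        period = pg.estimate_period(p)
        metrics["periodogram"] = {
            "period_h": period,
            "power_pct": pg.normalized_power(p),
        }
        with open(out_dir / "periodogram.csv", "w") as fh:
            fh.write("\n".join(_provenance(meta)) + "\n")
            fh.write("period_h,Qp,sig,power_pct\n")
            for row in zip(p.trial_periods, p.Qp, p.sig_line, p.power_pct):
                fh.write(",".join(f"{v:.6g}" for v in row) + "\n")

    if "simulate_sleep" in stages:
        sspec_kwargs = dict(config.get("sleep", {}))
        if seed is not None:
            sspec_kwargs["seed"] = seed
        sspec = syn.SleepSimSpec(**sspec_kwargs)
        trace = syn.gen_immobility(sspec)
        write_immobility_csv(trace, out_dir / "immobility.csv", meta)
        sleep_series = slp.score_sleep(trace, schedule=schedule)
        write_sleep_csv(sleep_series, out_dir / "sleep.csv", meta)
    elif "sleep_metrics" in stages and "immobility_csv" in config:
        trace = read_immobility_csv(config["immobility_csv"])
        sleep_series = slp.score_sleep(trace, schedule=schedule)

    if "sleep_metrics" in stages:
        totals = slp.sleep_totals(sleep_series)
        bouts = slp.sleep_bouts(sleep_series)
        metrics["sleep"] = {**totals, **slp.bout_stats(sleep_series, bouts)}

    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    with open(out_dir / "run.log", "w") as fh:
        fh.write(
            json.dumps(
                {"version": __version__, "seed": seed, "config": config, "hash": chash},
                indent=2,
                sort_keys=True,
                default=str,
            )
        )
    return metrics
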