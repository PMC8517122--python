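"""Waveform file I/O, resampling and breath segmentation.

Waveforms are exchanged as plain comma-separated text with a header of
``# key=value`` comment lines for metadata and columns ``time_s``,
``pressure_cmH2O``, ``volume_ml`` and optionally ``flow_ml_s``.  Time must
be strictly increasing with a consistent step; files sampled at a different
rate than the configured analysis step are resampled by linear
interpolation.  After segmentation, sample times are breath-relative
(t = 0 at segment start), so phases are estimable per breath.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from .errors import SegmentationError, WaveformFormatError
from .model import BreathRecord
from .waveforms import SampleGrid, Signal

__all__ = [
    "read_waveform",
    "write_waveform",
    "resample_record",
    "segment_breaths",
]

_COLUMNS = ("time_s", "pressure_cmH2O", "volume_ml")
_DT_TOLERANCE = 0.01  # relative spread of time steps accepted without resampling


def write_waveform(record: BreathRecord, path) -> None:
    """Write a record as delimited text with ``# key=value`` metadata lines."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.grid.times,
            "pressure_cmH2O": record.pressure.values,
            "volume_ml": record.volume.values,
        }
    )
    if record.flow is not None:
        df["flow_ml_s"] = record.flow.values
    lines = []
    for key, value in record.meta.items():
        if isinstance(value, str):
            lines.append(f"# {key}={value}")
        else:
            lines.append(f"# {key}={json.dumps(value)}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def _parse_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, raw = body.partition("=")
            try:
                meta[key.strip()] = json.loads(raw.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = raw.strip()
    return meta


def read_waveform(path, dt: float | None = None) -> BreathRecord:
    """Read a waveform file into a continuous :class:`BreathRecord`.

    Checks column presence, numeric parsability and strictly increasing
    time (errors name the offending line).  If the file's sampling step is
    inconsistent beyond 1% or differs from the requested ``dt``, all traces
    are linearly resampled onto a uniform grid.
    """
    path = Path(path)
    meta = _parse_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise WaveformFormatError(f"{path}: cannot parse as delimited text: {exc}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise WaveformFormatError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            bad = int(df.index[df[col].isna()][0]) if df[col].isna().any() else -1
            raise WaveformFormatError(
                f"{path}: column {col!r} contains non-numeric or missing data "
                f"(first bad data line {bad})"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise WaveformFormatError(f"{path}: need at least two samples")
    steps = np.diff(t)
    nonmono = np.nonzero(steps <= 0)[0]
    if nonmono.size:
        raise WaveformFormatError(
            f"{path}: time not strictly increasing at data line {int(nonmono[0]) + 1}"
        )
    file_dt = float(np.median(steps))
    uniform = np.all(np.abs(steps - file_dt) <= _DT_TOLERANCE * file_dt)
    target_dt = file_dt if dt is None else float(dt)
    need_resample = (not uniform) or abs(target_dt - file_dt) > 1e-9 * file_dt

    cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}
    if need_resample:
        t_new = np.arange(t[0], t[-1] + 0.5 * target_dt, target_dt)
        cols = {c: np.interp(t_new, t, v) for c, v in cols.items()}
        t = t_new
    grid = SampleGrid(dt=target_dt, n=len(t), t_start=float(t[0]))
    return BreathRecord(
        grid=grid,
        pressure=Signal(cols["pressure_cmH2O"], "cmH2O"),
        volume=Signal(cols["volume_ml"], "ml"),
        flow=Signal(cols["flow_ml_s"], "ml/s") if "flow_ml_s" in cols else None,
        meta=meta,
    )


def resample_record(record: BreathRecord, dt: float) -> BreathRecord:
    """Linearly resample all traces onto a uniform grid with step ``dt``."""
    t = record.grid.times
    t_new = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    grid = SampleGrid(dt=dt, n=len(t_new), t_start=float(t_new[0]),
                      burn_in_periods=record.grid.burn_in_periods)
    def interp(sig):
        return None if sig is None else Signal(
            np.interp(t_new, t, sig.values), sig.units
        )
    return BreathRecord(
        grid=grid,
        pressure=interp(record.pressure),
        volume=interp(record.volume),
        flow=interp(record.flow),
        meta=dict(record.meta),
    )


def segment_breaths(
    record: BreathRecord,
    min_period_s: float,
    trough_fraction: float = 0.3,
) -> list[BreathRecord]:
    """Split a continuous record into breaths at volume troughs.

    The end-expiratory baseline between breaths is the region where volume
    sits below ``min + trough_fraction * amplitude``; a new breath starts
    where the volume leaves that region (inspiration onset).  Boundaries
    closer than ``min_period_s`` are suppressed and leading/trailing
    fragments shorter than ``min_period_s`` are merged into their
    neighbours.  Each segment's time axis restarts at zero and its index is
    recorded in ``meta['breath_index']``.
    """
    v = record.volume.values
    dt = record.grid.dt
    n = record.grid.n
    if record.grid.span <= 2 * min_period_s:
        raise SegmentationError(
            f"record spans {record.grid.span:.3g} s; need > {2 * min_period_s:.3g} s"
        )
    amp = float(np.ptp(v))
    if amp <= max(1e-12, 1e-9 * float(np.max(np.abs(v), initial=0.0))):
        raise SegmentationError("volume trace is flat; no troughs to segment at")
    below = v < float(v.min()) + trough_fraction * amp
    if not below.any():
        raise SegmentationError(
            f"no volume troughs below min + {trough_fraction} * amplitude found"
        )
    # ends (exclusive) of contiguous below-threshold runs = inspiration onsets
    edges = np.nonzero(below[:-1] & ~below[1:])[0] + 1
    min_gap = max(1, round(min_period_s / dt))
    boundaries = []
    for idx in edges.tolist():
        if not boundaries or idx - boundaries[-1] >= min_gap:
            boundaries.append(idx)
    bounds = [0, *boundaries, n]
    segments = [
        (bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if bounds[i + 1] > bounds[i]
    ]
    # merge fragments at the edges into their neighbours
    if len(segments) > 1 and (segments[0][1] - segments[0][0]) * dt < min_period_s:
        segments[1] = (segments[0][0], segments[1][1])
        segments.pop(0)
    if len(segments) > 1 and (segments[-1][1] - segments[-1][0]) * dt < min_period_s:
        segments[-2] = (segments[-2][0], segments[-1][1])
        segments.pop()
    out = []
    for idx, (i0, i1) in enumerate(segments):
        grid = SampleGrid(
            dt=dt, n=i1 - i0, t_start=0.0,
            burn_in_periods=record.grid.burn_in_periods,
        )
        meta = dict(record.meta)
        meta.update(breath_index=idx, segment_start_s=float(record.grid.times[i0]))
        out.append(
            BreathRecord(
                grid=grid,
                pressure=Signal(record.pressure.values[i0:i1], record.pressure.units),
                volume=Signal(v[i0:i1], record.volume.units),
                flow=None if record.flow is None
                else Signal(record.flow.values[i0:i1], record.flow.units),
                meta=meta,
            )
        )
    return out
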