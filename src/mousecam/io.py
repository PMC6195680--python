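"""File I/O, frame-timestamp alignment, and body-speed derivation.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal.
HDF5 layout: one group per trace (e.g. /accel, /gyro, /lfp) with ``times``
and ``values`` datasets and a ``units`` attribute.
Frames: multi-page TIFF, or a directory of zero-padded PNGs, with a sidecar
CSV ``frame,timestamp_s``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile

from .containers import BodyTrack, EventTable, FrameStack, SpikeTrain, TimeSeries

__all__ = [
    "align_frame_timestamps",
    "body_speed",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_timeseries_h5",
    "write_timeseries_h5",
    "read_events_csv",
    "write_events_csv",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_bodytrack_csv",
    "write_bodytrack_csv",
    "read_framestack",
    "write_framestack",
]


def align_frame_timestamps(
    ttl_times: np.ndarray,
    clock_offsets: np.ndarray,
    drop_factor: float = 1.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Convert camera TTL pulse times to acquisition-clock frame times.

    Each camera frame triggers a TTL pulse on the neural recording system
    slightly after the GPU acquisition timestamp; the per-frame difference
    between the two clocks is saved alongside.  Frame time = TTL time minus
    the saved offset.

    Parameters
    ----------
    ttl_times : array
        TTL pulse times (s) on the acquisition clock, one per frame.
    clock_offsets : array
        Per-frame offset (s) between TTL arrival and frame acquisition.
    drop_factor : float
        Inter-frame intervals exceeding ``drop_factor`` × median interval
        are flagged as candidate dropped frames.

    Returns
    -------
    frame_times : array
        Acquisition-clock frame times, strictly increasing.
    dropped : boolean array, shape (n - 1,)
        True where the gap to the next frame suggests a dropped frame.
    """
    ttl_times = np.asarray(ttl_times, dtype=float)
    clock_offsets = np.asarray(clock_offsets, dtype=float)
    if ttl_times.shape != clock_offsets.shape:
        raise ValueError(
            f"{ttl_times.size} TTL pulses but {clock_offsets.size} clock offsets"
        )
    if not np.all(np.isfinite(clock_offsets)):
        raise ValueError("clock offsets must be finite")
    frame_times = ttl_times - clock_offsets
    dt = np.diff(frame_times)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ValueError(f"aligned frame times not strictly increasing at index {bad}")
    dropped = np.zeros(max(dt.size, 0), dtype=bool)
    if dt.size:
        dropped = dt > drop_factor * np.median(dt)
    return frame_times, dropped


def body_speed(track: BodyTrack, smooth_window: float = 0.25) -> BodyTrack:
    """Derive body speed (cm/s) from tracked positions.

    Speed is the magnitude of the centered finite-difference velocity
    (one-sided at the endpoints), boxcar-smoothed over ``smooth_window``
    seconds.  The default window sits below the 0.5 s quiescence criterion
    used by onset detection so smoothing cannot blur a locomotion bout
    across an onset window boundary.
    """
    if track.times.size < 2:
        raise ValueError("body_speed requires at least 2 samples")
    if not (np.all(np.isfinite(track.x)) and np.all(np.isfinite(track.y))):
        raise ValueError("positions must be finite")
    t, x, y = track.times, track.x, track.y
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    speed = np.hypot(vx, vy)
    dt = float(np.median(np.diff(t)))
    win = max(int(round(smooth_window / dt)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so the boxcar does not bias the endpoints toward zero
        padded = np.pad(speed, win, mode="reflect")
        speed = np.convolve(padded, kernel, mode="same")[win:-win]
    return BodyTrack(times=t.copy(), x=x.copy(), y=y.copy(), speed=speed)


# ---------------------------------------------------------------------------
# CSV / HDF5 trace I/O


def write_timeseries_csv(ts: TimeSeries, path) -> None:
    names = list(ts.channel_names) if ts.channel_names else [
        f"ch{i + 1}" for i in range(ts.n_channels)
    ]
    df = pd.DataFrame({"time_s": ts.times})
    for name, row in zip(names, ts.values):
        df[name] = row
    df.to_csv(path, index=False)


def read_timeseries_csv(path, units: str = "") -> TimeSeries:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time column not strictly increasing")
    chans = [c for c in df.columns if c != "time_s"]
    if not chans:
        raise ValueError(f"{path}: no channel columns")
    values = df[chans].to_numpy(dtype=float).T
    return TimeSeries(times=times, values=values, units=units, channel_names=chans)


def write_timeseries_h5(ts: TimeSeries, path, group: str = "trace") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("times", data=ts.times)
        g.create_dataset("values", data=ts.values)
        g.attrs["units"] = ts.units
        if ts.channel_names:
            g.attrs["channel_names"] = [str(c) for c in ts.channel_names]


def read_timeseries_h5(path, group: str = "trace") -> TimeSeries:
    with h5py.File(path, "r") as f:
        if group not in f:
            raise ValueError(f"{path}: no group {group!r}")
        g = f[group]
        times = g["times"][()]
        values = g["values"][()]
        units = str(g.attrs.get("units", ""))
        names = g.attrs.get("channel_names")
        if names is not None:
            names = [str(n) for n in names]
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}:{group}: times not strictly increasing")
    return TimeSeries(times=times, values=values, units=units, channel_names=names)


# ---------------------------------------------------------------------------
# Events / spikes / body track


def write_events_csv(events: EventTable, path) -> None:
    df = pd.DataFrame({"time_s": events.times, "label": events.labels})
    for key, val in events.attributes.items():
        df[key] = val
    df.to_csv(path, index=False)


def read_events_csv(path) -> EventTable:
    df = pd.read_csv(path)
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    attrs = {
        c: df[c].to_numpy() for c in df.columns if c not in ("time_s", "label")
    }
    return EventTable(
        times=df["time_s"].to_numpy(dtype=float),
        labels=df["label"].astype(str).tolist(),
        attributes=attrs,
    )


def write_spikes_csv(trains, path) -> None:
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.unit_id, t))
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(path, index=False)


def read_spikes_csv(path) -> list:
    df = pd.read_csv(path)
    for col in ("unit_id", "spike_time_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    return [
        SpikeTrain(unit_id=int(uid), spike_times=g["spike_time_s"].to_numpy(dtype=float))
        for uid, g in df.groupby("unit_id")
    ]


def write_bodytrack_csv(track: BodyTrack, path) -> None:
    df = pd.DataFrame({"time_s": track.times, "x_cm": track.x, "y_cm": track.y})
    if track.speed is not None:
        df["speed_cm_s"] = track.speed
    df.to_csv(path, index=False)


def read_bodytrack_csv(path) -> BodyTrack:
    df = pd.read_csv(path)
    for col in ("time_s", "x_cm", "y_cm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required {col!r} column")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time column not strictly increasing")
    speed = df["speed_cm_s"].to_numpy(dtype=float) if "speed_cm_s" in df.columns else None
    return BodyTrack(
        times=times,
        x=df["x_cm"].to_numpy(dtype=float),
        y=df["y_cm"].to_numpy(dtype=float),
        speed=speed,
    )


# ---------------------------------------------------------------------------
# Frame stacks


def write_framestack(stack: FrameStack, path, timestamps_path=None) -> None:
    """Write frames as multi-page TIFF (or PNG directory) + timestamp CSV."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.moveaxis(stack.frames, 2, 0))
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i in range(stack.n_frames):
            iio.imwrite(path / f"frame_{i:06d}.png", stack.frame(i))
    if timestamps_path is None:
        timestamps_path = _default_ts_path(path)
    pd.DataFrame(
        {"frame": np.arange(stack.n_frames), "timestamp_s": stack.timestamps}
    ).to_csv(timestamps_path, index=False)


def read_framestack(path, timestamps_path=None, pixel_pitch: float = 40.0) -> FrameStack:
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise ValueError(f"{path}: no frame_*.png files")
        frames = np.stack([iio.imread(f) for f in files], axis=-1)
    else:
        frames = np.moveaxis(tifffile.imread(path), 0, -1)
        if frames.ndim == 2:  # single page
            frames = frames[:, :, np.newaxis]
    if timestamps_path is None:
        timestamps_path = _default_ts_path(path)
    if os.path.exists(timestamps_path):
        df = pd.read_csv(timestamps_path)
        timestamps = df["timestamp_s"].to_numpy(dtype=float)
    else:
        timestamps = np.arange(frames.shape[2], dtype=float)
    return FrameStack(frames=frames, timestamps=timestamps, pixel_pitch=pixel_pitch)


def _default_ts_path(path: Path) -> Path:
    return path.with_suffix("").parent / (path.with_suffix("").name + "_timestamps.csv")
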