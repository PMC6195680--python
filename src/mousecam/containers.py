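"""In-memory containers shared by all analysis modules.

All times are seconds on the neural-acquisition clock; conversions from
camera or tracker clocks happen at I/O boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "FrameStack",
    "EventTable",
    "BodyTrack",
    "SpikeTrain",
    "StateLabels",
    "PupilFit",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class TimeSeries:
    """Multichannel regularly- or irregularly-sampled time series.

    Parameters
    ----------
    times : array, shape (n,)
        Sample times in seconds, strictly increasing.
    values : array, shape (n_channels, n)
        One row per channel. A 1-D array is promoted to a single channel.
    rate : float, optional
        Nominal sampling rate in Hz. When given it must agree with the
        median time step within 1%.
    units : str
        Physical units of the values (e.g. ``"g"``, ``"deg/s"``, ``"uV"``).
    channel_names : sequence of str, optional
    metadata : dict
        Free-form annotations (e.g. edge-contamination masks).
    """

    times: np.ndarray
    values: np.ndarray
    rate: Optional[float] = None
    units: str = ""
    channel_names: Optional[Sequence[str]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[np.newaxis, :]
        if vals.ndim != 2:
            raise ValueError(f"values must be 1-D or 2-D, got shape {vals.shape}")
        if vals.shape[1] != self.times.size:
            raise ValueError(
                f"values has {vals.shape[1]} samples but times has {self.times.size}"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(f"times not strictly increasing at index {bad}")
        self.values = vals
        if self.rate is not None and self.times.size > 1:
            med = float(np.median(np.diff(self.times)))
            if abs(1.0 / med - self.rate) > 0.01 * self.rate:
                raise ValueError(
                    f"rate {self.rate} Hz inconsistent with median step {med:.6g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size > 1 else 0.0

    def channel(self, i: int) -> np.ndarray:
        return self.values[i]

    def copy_with(self, **kw) -> "TimeSeries":
        args = dict(
            times=self.times.copy(),
            values=self.values.copy(),
            rate=self.rate,
            units=self.units,
            channel_names=self.channel_names,
            metadata=dict(self.metadata),
        )
        args.update(kw)
        return TimeSeries(**args)


@dataclass
class FrameStack:
    """Stack of 8-bit video frames with per-frame timestamps.

    frames : array, shape (height, width, n_frames), uint8
    timestamps : array, shape (n_frames,), seconds, strictly increasing
    pixel_pitch : float, µm per pixel (> 0)
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_pitch: float = 40.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (h, w, n), got shape {self.frames.shape}")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.round(self.frames), 0, 255).astype(np.uint8)
        self.timestamps = _as_1d(self.timestamps, "timestamps")
        if self.timestamps.size != self.frames.shape[2]:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps not strictly increasing")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[:, :, i]


@dataclass
class EventTable:
    """Timestamped events with labels and optional per-event attributes."""

    times: np.ndarray
    labels: Optional[Sequence[str]] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        if self.labels is None:
            self.labels = ["event"] * self.times.size
        self.labels = list(self.labels)
        if len(self.labels) != self.times.size:
            raise ValueError("labels and times must have the same length")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be non-decreasing")
        for key, val in self.attributes.items():
            arr = np.asarray(val)
            if arr.shape[0] != self.times.size:
                raise ValueError(f"attribute {key!r} length mismatch")
            self.attributes[key] = arr

    def __len__(self) -> int:
        return self.times.size

    def select(self, mask) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        return EventTable(
            times=self.times[mask],
            labels=[l for l, m in zip(self.labels, mask) if m],
            attributes={k: v[mask] for k, v in self.attributes.items()},
        )


@dataclass
class BodyTrack:
    """Arena-frame body position from an external tracker, with derived speed."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = _as_1d(self.times, "times")
        self.x = _as_1d(self.x, "x")
        self.y = _as_1d(self.y, "y")
        if not (self.times.size == self.x.size == self.y.size):
            raise ValueError("times, x, y must have the same length")
        if self.speed is not None:
            self.speed = _as_1d(self.speed, "speed")
            if self.speed.size != self.times.size:
                raise ValueError("speed length must equal times length")
            if np.any(self.speed < 0):
                raise ValueError("speed must be non-negative")


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit; sorting itself is an upstream input."""

    unit_id: int
    spike_times: np.ndarray
    quality: str = "SU"  # "SU" or "MU"

    def __post_init__(self):
        self.spike_times = np.sort(_as_1d(self.spike_times, "spike_times"))
        # duplicates closer than 0.1 ms are physically impossible refractory violations
        if self.spike_times.size > 1:
            dt = np.diff(self.spike_times)
            if np.any(dt < 1e-4):
                self.spike_times = np.delete(self.spike_times, np.flatnonzero(dt < 1e-4) + 1)

    def __len__(self) -> int:
        return self.spike_times.size


STATE_ORDER = ("active", "quiescent", "grooming", "eating")


@dataclass
class StateLabels:
    """Behavioral-state interval annotations.

    intervals : list of (start_s, end_s, state) with non-overlapping spans
    of at least ``min_duration`` seconds each.
    """

    intervals: list
    min_duration: float = 2.0

    def __post_init__(self):
        ivs = []
        for start, end, state in self.intervals:
            start, end = float(start), float(end)
            if end - start < self.min_duration - 1e-9:
                raise ValueError(
                    f"state interval ({start}, {end}) shorter than {self.min_duration} s"
                )
            ivs.append((start, end, str(state)))
        ivs.sort(key=lambda t: t[0])
        for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
            if s1 < e0 - 1e-9:
                raise ValueError(f"overlapping intervals at {s1}")
        self.intervals = ivs

    def state_at(self, t: float) -> Optional[str]:
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        return None

    def states_at(self, times: np.ndarray) -> np.ndarray:
        """Vectorized lookup; returns object array with None outside intervals."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, None, dtype=object)
        for start, end, state in self.intervals:
            out[(times >= start) & (times < end)] = state
        return out

    def occupancy(self, order: Sequence[str] = STATE_ORDER) -> np.ndarray:
        """Fraction of annotated time per state, normalized to sum 1."""
        tot = {s: 0.0 for s in order}
        for start, end, state in self.intervals:
            if state in tot:
                tot[state] += end - start
        vec = np.array([tot[s] for s in order])
        total = vec.sum()
        return vec / total if total > 0 else vec


@dataclass
class PupilFit:
    """Ellipse fit to the pupil in one frame (axes are full lengths, px)."""

    frame_index: int
    center_x: float = np.nan
    center_y: float = np.nan
    major_axis: float = np.nan
    minor_axis: float = np.nan
    angle: float = np.nan  # degrees in [0, 180)
    mean_intensity: float = np.nan
    valid: bool = False
    reason: str = ""

    def __post_init__(self):
        if self.valid:
            if not (self.major_axis >= self.minor_axis > 0):
                raise ValueError("valid fit requires major >= minor > 0")
            self.angle = float(self.angle) % 180.0

    @property
    def area(self) -> float:
        """Ellipse area π·a·b/4 from the full axis lengths."""
        return np.pi * self.major_axis * self.minor_axis / 4.0
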