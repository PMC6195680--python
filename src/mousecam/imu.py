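"""Head orientation and head-movement analysis from inertial signals.

A 3-axis accelerometer rigidly attached to the head measures the sum of
gravity and inertial acceleration in the head frame (x naso-occipital,
y interaural, z ventral-dorsal).  The slowly varying gravity component,
isolated by a zero-phase 2 Hz low-pass filter, encodes static head pitch
and roll; the residual encodes head movement.  The movement magnitude

    |a(t)| = sqrt(ax(t)^2 + ay(t)^2 + az(t)^2)

of the gravity-subtracted signal, smoothed at 2 Hz, is thresholded
(default 0.0625 g) to detect head-movement onsets: an upward crossing
counts as an onset only if the magnitude stayed below threshold for at
least 0.5 s before and above for at least 0.5 s after the crossing.

Angle conventions (documented, since only magnitudes are defined by the
plane-angle construction): pitch > 0 when the nose is above horizontal,
roll > 0 when the right ear is below horizontal.  Pitch is the angle
between the gravity vector and the y/z plane; roll is the bank angle
about the naso-occipital axis, which coincides with the plane angle at
zero pitch and keeps the (pitch, roll) -> gravity map invertible.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .containers import EventTable, TimeSeries

__all__ = [
    "extract_gravity",
    "gravity_from_angles",
    "pitch_roll",
    "movement_magnitude",
    "detect_onsets",
    "integrate_yaw",
    "orientation_histogram",
    "OrientationHistogram",
]

EDGE_SECONDS = 1.0  # first/last second after zero-phase filtering is flagged


def _require_rate(ts: TimeSeries) -> float:
    if ts.rate is not None:
        return float(ts.rate)
    dt = np.diff(ts.times)
    if dt.size == 0:
        raise ValueError("cannot infer sampling rate from a single sample")
    if np.ptp(dt) > 0.01 * np.median(dt):
        raise ValueError("non-uniform sampling; resample first")
    return 1.0 / float(np.median(dt))


def extract_gravity(accel: TimeSeries, cutoff: float = 2.0, order: int = 2) -> TimeSeries:
    """Estimate the gravity component of an accelerometer trace.

    Zero-phase (forward-backward) Butterworth low-pass per channel,
    default second order with 2 Hz cutoff.  DC gain is exactly 1, so a
    static orientation passes through unchanged.  The first and last
    second are flagged as edge-contaminated in ``metadata['edge_mask']``.
    """
    rate = _require_rate(accel)
    if rate < 10 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz < 10× cutoff {cutoff} Hz")
    if accel.duration < 3.0 / cutoff:
        raise ValueError("trace shorter than 3 filter time constants")
    b, a = butter(order, cutoff, btype="low", fs=rate)
    filtered = filtfilt(b, a, accel.values, axis=1)
    edge = np.zeros(accel.n_samples, dtype=bool)
    n_edge = int(round(EDGE_SECONDS * rate))
    edge[:n_edge] = True
    edge[accel.n_samples - n_edge:] = True
    out = accel.copy_with(values=filtered)
    out.metadata["edge_mask"] = edge
    return out


def gravity_from_angles(pitch_deg, roll_deg) -> np.ndarray:
    """Unit gravity vector in the head frame for given pitch/roll (degrees).

    Forward model used by the synthetic generators and the recovery
    oracle: a level head measures g = (0, 0, -1); pitching the nose up by
    p rotates gravity onto -x; rolling the right ear down by r rotates
    the remainder onto -y.

    Returns array of shape (3, n) (or (3,) for scalars).
    """
    p = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    r = np.deg2rad(np.asarray(roll_deg, dtype=float))
    gx = -np.sin(p)
    gy = -np.cos(p) * np.sin(r)
    gz = -np.cos(p) * np.cos(r)
    return np.stack([gx, gy, gz])


def pitch_roll(gravity: TimeSeries, min_norm: float = 0.5) -> TimeSeries:
    """Head pitch and roll (degrees) from a 3-channel gravity estimate.

    pitch = asin(-gx / |g|) — the signed angle between gravity and the
    y/z plane (normal ex); roll = atan2(-gy, -gz) — the bank angle about
    the naso-occipital axis.  Invariant to |g| scaling.  Samples with
    |g| below ``min_norm`` (in g) are flagged invalid in
    ``metadata['valid']`` rather than raising.
    """
    if gravity.n_channels != 3:
        raise ValueError("gravity must have 3 channels (x, y, z)")
    g = gravity.values
    norm = np.linalg.norm(g, axis=0)
    valid = norm > min_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm > 0, g / np.where(norm > 0, norm, 1.0), 0.0)
        pitch = np.rad2deg(np.arcsin(np.clip(-unit[0], -1.0, 1.0)))
        roll = np.rad2deg(np.arctan2(-unit[1], -unit[2]))
    pitch = np.where(valid, pitch, np.nan)
    roll = np.where(valid, roll, np.nan)
    out = TimeSeries(
        times=gravity.times.copy(),
        values=np.vstack([pitch, roll]),
        rate=gravity.rate,
        units="deg",
        channel_names=["pitch", "roll"],
        metadata={"valid": valid,
                  "convention": "pitch: nose-up positive; roll: right-ear-down positive"},
    )
    if "edge_mask" in gravity.metadata:
        out.metadata["edge_mask"] = gravity.metadata["edge_mask"]
    return out


def movement_magnitude(
    accel: TimeSeries,
    gravity: TimeSeries,
    smooth_cutoff: Optional[float] = 2.0,
) -> TimeSeries:
    """Magnitude of head movement: |accel - gravity| per sample, in g.

    The Euclidean norm of the gravity-subtracted 3-vector is computed
    per sample and then smoothed with a zero-phase low-pass (default
    2 Hz cutoff; pass ``smooth_cutoff=None`` for the raw norm).
    """
    if accel.n_samples != gravity.n_samples or not np.allclose(
        accel.times, gravity.times
    ):
        raise ValueError("accel and gravity must share a time base")
    residual = accel.values - gravity.values
    mag = np.linalg.norm(residual, axis=0)
    if smooth_cutoff is not None:
        rate = _require_rate(accel)
        b, a = butter(2, smooth_cutoff, btype="low", fs=rate)
        mag = filtfilt(b, a, mag)
    return TimeSeries(
        times=accel.times.copy(),
        values=mag,
        rate=accel.rate,
        units="g",
        channel_names=["magnitude"],
    )


def detect_onsets(
    signal: TimeSeries,
    threshold: float,
    min_pre_below: float = 0.5,
    min_post_above: float = 0.5,
    exclude_mask: Optional[np.ndarray] = None,
    label: str = "onset",
) -> EventTable:
    """Detect movement onsets as sustained upward threshold crossings.

    A sample is an onset when it is the first sample strictly above
    ``threshold`` after the signal stayed at or below threshold for at
    least ``min_pre_below`` seconds, and the signal then stays strictly
    above threshold for at least ``min_post_above`` seconds.  Crossings
    whose pre/post window leaves the recording or intersects a masked
    sample (e.g. body speed >= 1 cm/s) are dropped.

    The same rule serves head-movement onsets (0.0625 g, 0.5/0.5 s),
    whisking onsets (0.5/0.1 s) and rotational-movement onsets (15 °/s).
    """
    if signal.n_channels != 1:
        raise ValueError("detect_onsets expects a 1-channel signal")
    x = signal.values[0]
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    t = signal.times
    n = x.size
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.size != n:
            raise ValueError("exclude_mask must align with the signal")

    above = x > threshold
    # candidate crossings: first sample above after a sample not above
    cand = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    rate = _require_rate(signal)
    n_pre = int(round(min_pre_below * rate))
    n_post = int(round(min_post_above * rate))

    onset_times = []
    for i in cand:
        if i - n_pre < 0 or i + n_post > n:
            continue
        if np.any(above[i - n_pre:i]):
            continue
        if not np.all(above[i:i + n_post]):
            continue
        if exclude_mask is not None and np.any(exclude_mask[i - n_pre:i + n_post]):
            continue
        onset_times.append(t[i])
    return EventTable(times=np.array(onset_times), labels=[label] * len(onset_times))


def integrate_yaw(gyro_yaw: TimeSeries, tau: float = 1.0) -> TimeSeries:
    """Approximate angular yaw position by leaky integration.

    The yaw angular-velocity signal (°/s) is convolved with a causal
    exponential decay kernel exp(-t/τ), τ = 1 s by default, truncated at
    7τ.  A velocity step of ω settles at ωτ; an impulse of area A reads
    out as A·exp(-t/τ).
    """
    if gyro_yaw.n_channels != 1:
        raise ValueError("integrate_yaw expects the 1-channel yaw velocity")
    rate = _require_rate(gyro_yaw)
    dt = 1.0 / rate
    kt = np.arange(0, 7 * tau + dt / 2, dt)
    kernel = np.exp(-kt / tau)
    # trapezoidal weight on the leading sample: the discrete sum then matches
    # the continuous convolution integral to O((dt/tau)^2)
    kernel[0] *= 0.5
    pos = np.convolve(gyro_yaw.values[0], kernel)[: gyro_yaw.n_samples] * dt
    return TimeSeries(
        times=gyro_yaw.times.copy(),
        values=pos,
        rate=gyro_yaw.rate,
        units="deg",
        channel_names=["yaw_position"],
    )


class OrientationHistogram:
    """Spherical histogram of head-orientation (gravity-direction) samples.

    Bins are a regular elevation × azimuth grid (default 5°); counts are
    normalized by the total count and by each bin's solid angle so the
    density integrates to 1 over the sphere.  ``log_density`` is log10 of
    the density with empty bins set to NaN.
    """

    def __init__(self, elevation_edges, azimuth_edges, density):
        self.elevation_edges = np.asarray(elevation_edges)
        self.azimuth_edges = np.asarray(azimuth_edges)
        self.density = np.asarray(density)
        with np.errstate(divide="ignore"):
            self.log_density = np.where(
                self.density > 0, np.log10(np.where(self.density > 0, self.density, 1)),
                np.nan,
            )

    @property
    def bin_solid_angles(self) -> np.ndarray:
        el = np.deg2rad(self.elevation_edges)
        az = np.deg2rad(self.azimuth_edges)
        dphi = np.diff(az)
        band = np.diff(np.sin(el))
        return np.outer(band, dphi)

    def integral(self) -> float:
        return float(np.sum(self.density * self.bin_solid_angles))


def orientation_histogram(gravity: TimeSeries, bin_deg: float = 5.0) -> OrientationHistogram:
    """Histogram gravity directions on the sphere, solid-angle normalized.

    Samples are converted to spherical coordinates (elevation Θ from the
    horizontal plane, azimuth Φ in the x/y plane) and binned on a
    ``bin_deg`` grid; counts are divided by total count and quadrangle
    solid angle.
    """
    if gravity.n_channels != 3:
        raise ValueError("gravity must have 3 channels")
    g = gravity.values
    norm = np.linalg.norm(g, axis=0)
    ok = norm > 0
    if "valid" in gravity.metadata:
        ok &= np.asarray(gravity.metadata["valid"], dtype=bool)
    if not np.any(ok):
        raise ValueError("no valid samples to histogram")
    u = g[:, ok] / norm[ok]
    elevation = np.rad2deg(np.arcsin(np.clip(u[2], -1, 1)))
    azimuth = np.rad2deg(np.arctan2(u[1], u[0]))
    el_edges = np.arange(-90.0, 90.0 + bin_deg / 2, bin_deg)
    az_edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    counts, _, _ = np.histogram2d(elevation, azimuth, bins=[el_edges, az_edges])
    hist = OrientationHistogram(el_edges, az_edges, counts)
    omega = hist.bin_solid_angles
    density = counts / counts.sum() / omega
    return OrientationHistogram(el_edges, az_edges, density)
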