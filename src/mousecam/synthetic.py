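"""Synthetic session generators with full ground truth.

Every downstream analysis (orientation recovery, pupil fitting, state
segmentation, eye-head regression, event-aligned spiking) can be tested
against these generators without any animal data.  Each generator is
fully deterministic given its seed and returns the ground truth its
consumer's parameter-recovery test needs.

What is emulated, and what is not: the accelerometer model is gravity in
the head frame (smooth random-walk orientation) plus state-specific
narrowband oscillations and white noise — it reproduces the spectral
signatures that behavioral segmentation exploits, not the kinematics of
real grooming; the eye-video model is a dark ellipse with an optional
specular reflection disk on a bright background — it reproduces the
geometry the pupil fitter sees, not iris texture or eyelids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .containers import EventTable, FrameStack, SpikeTrain, StateLabels, TimeSeries
from .imu import gravity_from_angles

__all__ = [
    "STATE_BANDS",
    "gen_orientation_walk",
    "gen_accel_session",
    "gen_eye_video",
    "render_eye_frame",
    "gen_eyehead_dataset",
    "gen_spike_data",
    "LAG_GRID_S",
    "N_LAGS",
]

# Lag grid of the eye-head model: -500 ... 0 ms, step 25 ms (21 lags).
LAG_GRID_S = np.arange(-0.500, 0.0 + 1e-9, 0.025)
N_LAGS = LAG_GRID_S.size

# Per-state accelerometer signatures: (band center Hz or (lo, hi) band, amplitude g).
# Grooming strokes are periodic (~6 Hz), chewing ~4 Hz, active exploration is
# broadband, quiescence is near-silent.  The spectral centers are free
# configuration consistent with the qualitative per-state spectra, not
# measured constants.
STATE_BANDS: Dict[str, dict] = {
    "active": {"band": (2.0, 20.0), "amplitude": 0.15},
    "quiescent": {"band": None, "amplitude": 0.0},
    "grooming": {"band": 6.0, "amplitude": 0.12},
    "eating": {"band": 4.0, "amplitude": 0.12},
}

# Orientation random walk: Gaussian increments on pitch/roll, reflected at
# ±60°.  Quiescence keeps the head nearly still.
WALK_SD_DEG_PER_SQRT_S = {"active": 2.0, "quiescent": 0.2, "grooming": 1.0, "eating": 0.5}
WALK_REFLECT_DEG = 60.0


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    # reflect a random walk into [-bound, bound]
    x = np.mod(x + bound, 4 * bound)
    x = np.where(x > 2 * bound, 4 * bound - x, x)
    return x - bound


def gen_orientation_walk(
    times: np.ndarray,
    rng: np.random.Generator,
    sd_per_sqrt_s: np.ndarray | float = 2.0,
    bound: float = WALK_REFLECT_DEG,
) -> Tuple[np.ndarray, np.ndarray]:
    """Smooth reflected random walk for (pitch, roll), degrees."""
    dt = np.diff(times, prepend=times[0] - (times[1] - times[0]))
    sd = np.broadcast_to(np.asarray(sd_per_sqrt_s, dtype=float), times.shape)
    steps = rng.standard_normal((2, times.size)) * sd * np.sqrt(dt)
    pitch = _reflect(np.cumsum(steps[0]), bound)
    roll = _reflect(np.cumsum(steps[1]), bound)
    return pitch, roll


def _narrowband_noise(n: int, rate: float, band: Tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    b, a = butter(4, band, btype="band", fs=rate)
    x = filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_accel_session(
    state_schedule: Sequence[Tuple[str, float]],
    rate: float = 100.0,
    seed: int = 0,
    noise_sd: float = 0.004,
    state_bands: Optional[Dict[str, dict]] = None,
) -> Tuple[TimeSeries, StateLabels, TimeSeries]:
    """Generate a 3-axis accelerometer session with labeled behavioral states.

    The trace is gravity in the head frame (from a smooth random-walk
    orientation) plus a state-specific oscillation and white noise of SD
    ``noise_sd`` g.  State segments must each last at least 2 s.

    Returns
    -------
    accel : TimeSeries (3 × n, g)
    labels : StateLabels
    orientation : TimeSeries, ground-truth (pitch, roll) in degrees
    """
    bands = dict(STATE_BANDS)
    if state_bands:
        bands.update(state_bands)
    for state, _ in state_schedule:
        if state not in bands:
            raise ValueError(f"unknown state name {state!r}")
    rng = np.random.default_rng(seed)
    durations = np.array([d for _, d in state_schedule], dtype=float)
    duration = durations.sum()
    n = int(round(duration * rate))
    times = np.arange(n) / rate

    edges = np.concatenate([[0.0], np.cumsum(durations)])
    intervals = [
        (edges[i], edges[i + 1], state) for i, (state, _) in enumerate(state_schedule)
    ]
    labels = StateLabels(intervals)

    # per-sample walk SD follows the behavioral state
    walk_sd = np.empty(n)
    osc = np.zeros((3, n))
    for start, end, state in intervals:
        sel = (times >= start) & (times < end)
        walk_sd[sel] = WALK_SD_DEG_PER_SQRT_S.get(state, 1.0)
        cfg = bands[state]
        amp, bandspec = cfg["amplitude"], cfg["band"]
        if amp <= 0 or bandspec is None:
            continue
        m = int(sel.sum())
        if isinstance(bandspec, tuple):
            comp = np.stack([_narrowband_noise(m, rate, bandspec, rng) for _ in range(3)])
        else:
            f0 = float(bandspec)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            tloc = times[sel]
            comp = np.stack([np.sin(2 * np.pi * f0 * tloc + ph) for ph in phases])
        osc[:, sel] = amp * comp

    pitch, roll = gen_orientation_walk(times, rng, sd_per_sqrt_s=walk_sd)
    gravity = gravity_from_angles(pitch, roll)
    accel_vals = gravity + osc + noise_sd * rng.standard_normal((3, n))

    accel = TimeSeries(times=times, values=accel_vals, rate=rate, units="g",
                       channel_names=["ax", "ay", "az"])
    orientation = TimeSeries(times=times, values=np.vstack([pitch, roll]),
                             rate=rate, units="deg", channel_names=["pitch", "roll"])
    return accel, labels, orientation


# ---------------------------------------------------------------------------
# Eye video rendering


def render_eye_frame(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    axes: Tuple[float, float],
    angle_deg: float,
    background: float = 200.0,
    pupil_intensity: float = 30.0,
    reflection: Optional[Tuple[float, float, float]] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    supersample: int = 4,
) -> np.ndarray:
    """Render one eye frame: dark pupil ellipse on a bright background.

    ``center`` is (x, y) px, ``axes`` are full major/minor lengths px,
    ``angle_deg`` is the major-axis angle.  ``reflection`` is an optional
    saturated disk (cx, cy, radius).  Anti-aliased by ``supersample``×
    area averaging, so subpixel edges survive into the 8-bit frame.
    """
    h, w = shape
    s = supersample
    yy, xx = np.mgrid[0:h * s, 0:w * s]
    # coordinates of supersampled pixel centers in original pixel units
    xs = (xx + 0.5) / s - 0.5
    ys = (yy + 0.5) / s - 0.5
    a, b = axes[0] / 2.0, axes[1] / 2.0
    th = np.deg2rad(angle_deg)
    dx, dy = xs - center[0], ys - center[1]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    img = np.full((h * s, w * s), background, dtype=float)
    img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = pupil_intensity
    if reflection is not None:
        cx, cy, r = reflection
        img[(xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2] = 255.0
    frame = img.reshape(h, s, w, s).mean(axis=(1, 3))
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        frame = frame + rng.normal(0, noise_sd, frame.shape)
    return np.clip(np.round(frame), 0, 255).astype(np.uint8)


def gen_eye_video(
    trajectory_deg: np.ndarray,
    frame_shape: Tuple[int, int] = (120, 160),
    px_per_deg: float = 3.0,
    pupil_axes: Tuple[float, float] = (40.0, 30.0),
    pupil_angle: float = 0.0,
    reflection_radius: float = 0.0,
    noise_sd: float = 0.0,
    frame_rate: float = 50.0,
    pixel_pitch: float = 40.0,
    seed: int = 0,
) -> Tuple[FrameStack, list]:
    """Render an eye-video stack following a (horizontal, vertical) ° trajectory.

    The pupil center moves linearly with eye position at ``px_per_deg``
    (default 3.0 px/°, a configurable projection).  An optional saturated
    reflection disk sits at a fixed position overlapping the pupil edge.
    Returns the stack and the exact per-frame ellipse parameters.
    """
    from .containers import PupilFit

    traj = np.atleast_2d(np.asarray(trajectory_deg, dtype=float))
    if traj.shape[1] == 2 and traj.shape[0] != 2:
        traj = traj.T
    n = traj.shape[1]
    h, w = frame_shape
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    centers_x = cx0 + traj[0] * px_per_deg
    centers_y = cy0 - traj[1] * px_per_deg  # vertical ° up = image y down
    a = pupil_axes[0] / 2.0
    bad = np.flatnonzero(
        (centers_x - a < 0) | (centers_x + a > w - 1)
        | (centers_y - a < 0) | (centers_y + a > h - 1)
    )
    if bad.size:
        raise ValueError(f"pupil exits frame at indices {bad.tolist()[:10]}")
    rng = np.random.default_rng(seed)
    frames = np.empty((h, w, n), dtype=np.uint8)
    truths = []
    for i in range(n):
        refl = None
        if reflection_radius > 0:
            # illumination glint straddling the pupil boundary on the major axis
            th = np.deg2rad(pupil_angle)
            refl = (centers_x[i] + pupil_axes[0] / 2.0 * np.cos(th),
                    centers_y[i] + pupil_axes[0] / 2.0 * np.sin(th),
                    reflection_radius)
        frames[:, :, i] = render_eye_frame(
            (h, w), (centers_x[i], centers_y[i]),
            pupil_axes, pupil_angle, reflection=refl,
            noise_sd=noise_sd, rng=rng,
        )
        truths.append(PupilFit(
            frame_index=i, center_x=centers_x[i], center_y=centers_y[i],
            major_axis=max(pupil_axes), minor_axis=min(pupil_axes),
            angle=pupil_angle % 180.0, mean_intensity=30.0, valid=True,
        ))
    stack = FrameStack(frames=frames, timestamps=np.arange(n) / frame_rate,
                       pixel_pitch=pixel_pitch)
    return stack, truths


# ---------------------------------------------------------------------------
# Eye-head forward model


@dataclass
class EyeHeadTruth:
    """Ground truth returned by :func:`gen_eyehead_dataset`."""

    k_pitch: np.ndarray
    k_roll: np.ndarray
    k_yaw: Optional[np.ndarray]
    k0: float
    noise_sd: float
    eye_noiseless: np.ndarray
    signal_variance: float


def _smooth_signal(n: int, rate: float, rng: np.random.Generator,
                   cutoff: float = 15.0, sd_deg: float = 15.0) -> np.ndarray:
    # head-motion surrogate with power up to `cutoff`; enough fast content
    # that the per-lag weights of the forward model stay identifiable
    b, a = butter(2, min(cutoff, 0.45 * rate), btype="low", fs=rate)
    x = filtfilt(b, a, rng.standard_normal(n))
    return sd_deg * x / x.std()


def gen_eyehead_dataset(
    k_pitch: np.ndarray,
    k_roll: np.ndarray,
    k0: float = 0.0,
    k_yaw: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    duration: float = 400.0,
    rate: float = 50.0,
    head_sd_deg: float = 15.0,
    seed: int = 0,
) -> Tuple[TimeSeries, TimeSeries, EyeHeadTruth]:
    """Generate head orientation and eye position from the lagged linear model.

    Eye position at sample i is the inner product of the weight vectors
    with the head pitch/roll (and optionally leaky-integrated yaw)
    history at lags -500…0 ms (step 25 ms), plus the offset k0 and
    Gaussian noise of SD ``noise_sd`` degrees:

        p_i = k_pitch' u_i + k_roll' v_i (+ k_yaw' w_i) + k0 + N(0, σ²)

    Head signals are smooth (2 Hz) Gaussian processes with SD
    ``head_sd_deg``.  Returns head orientation (2 or 3 channels), the
    eye trace, and the ground truth including the noiseless eye signal.
    """
    k_pitch = np.asarray(k_pitch, dtype=float)
    k_roll = np.asarray(k_roll, dtype=float)
    for name, k in (("k_pitch", k_pitch), ("k_roll", k_roll)):
        if k.size != N_LAGS:
            raise ValueError(f"{name} must have length {N_LAGS}, got {k.size}")
    if k_yaw is not None:
        k_yaw = np.asarray(k_yaw, dtype=float)
        if k_yaw.size != N_LAGS:
            raise ValueError(f"k_yaw must have length {N_LAGS}, got {k_yaw.size}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    times = np.arange(n) / rate
    pitch = _smooth_signal(n, rate, rng, sd_deg=head_sd_deg)
    roll = _smooth_signal(n, rate, rng, sd_deg=head_sd_deg)
    chans = [pitch, roll]
    names = ["pitch", "roll"]
    weights = [k_pitch, k_roll]
    if k_yaw is not None:
        yaw = _smooth_signal(n, rate, rng, sd_deg=head_sd_deg)
        chans.append(yaw)
        names.append("yaw")
        weights.append(k_yaw)

    eye = np.full(n, float(k0))
    lag_idx_f = LAG_GRID_S * rate
    for sig, k in zip(chans, weights):
        for j, lf in enumerate(lag_idx_f):
            shifted = np.interp(times + LAG_GRID_S[j], times, sig,
                                left=np.nan, right=np.nan)
            eye = eye + k[j] * shifted
    valid = np.isfinite(eye)
    eye_times, eye = times[valid], eye[valid]
    signal_var = float(np.var(eye))
    noisy = eye + noise_sd * rng.standard_normal(eye.size)

    # head trace is kept over the full span so every eye sample has the
    # complete 500 ms history it was generated from
    head = TimeSeries(times=times, values=np.vstack(chans), rate=rate,
                      units="deg", channel_names=names)
    eye_ts = TimeSeries(times=eye_times, values=noisy, rate=rate, units="deg",
                        channel_names=["eye"])
    truth = EyeHeadTruth(k_pitch=k_pitch, k_roll=k_roll, k_yaw=k_yaw, k0=float(k0),
                         noise_sd=noise_sd, eye_noiseless=eye,
                         signal_variance=signal_var)
    return head, eye_ts, truth


# ---------------------------------------------------------------------------
# Spike trains


def gen_spike_data(
    onsets: EventTable,
    baseline_rate: float,
    mi_true: Sequence[float],
    duration: float,
    seed: int = 0,
    post_window: float = 1.0,
) -> List[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains with a prescribed modulation index.

    The firing rate steps from ``baseline_rate`` to
    baseline × (1 + MI)/(1 − MI) for exactly ``post_window`` seconds
    after each onset, which makes the expected pre/post contrast
    (Npost − Npre)/(Npost + Npre) equal to ``mi_true`` analytically.
    """
    if not baseline_rate > 0:
        raise ValueError("baseline rate must be > 0")
    mi_true = np.asarray(mi_true, dtype=float)
    if np.any(np.abs(mi_true) >= 1):
        raise ValueError("|MI| must be < 1")
    if len(onsets) > 1 and np.any(np.diff(onsets.times) < 2 * post_window):
        warnings.warn("onsets closer than 2 s: pre/post windows overlap")
    rng = np.random.default_rng(seed)
    trains = []
    for uid, mi in enumerate(mi_true):
        ratio = (1 + mi) / (1 - mi)
        peak = baseline_rate * max(ratio, 1.0)
        # thinning: generate at the max rate, accept by local rate
        n_cand = rng.poisson(peak * duration)
        cand = np.sort(rng.uniform(0, duration, n_cand))
        local = np.full(cand.size, baseline_rate)
        for t0 in onsets.times:
            local[(cand > t0) & (cand <= t0 + post_window)] = baseline_rate * ratio
        keep = rng.uniform(0, peak, cand.size) < local
        trains.append(SpikeTrain(unit_id=uid, spike_times=cand[keep]))
    return trains
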