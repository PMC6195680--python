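"""Camera-image stability analysis and whisker-pad movement extraction.

The head-mounted camera is checked for mechanical stability by
registering a region of interest (typically containing part of the
implant) of every frame against the pixelwise-average reference ROI.
Registration is integer-pixel exhaustive correlation within a search
radius; frames whose mean ROI brightness deviates more than 3 SD (e.g.
camera view blocked during grooming) are excluded.  The stability
metric is the inter-frame image movement: the change in 2-D
displacement between successive frames, in µm.

Whisker-pad movement is the spatial average of dense optical flow over
a rectangular ROI containing the pad; analyses use the horizontal
(azimuthal) component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import welch
from skimage.filters import gaussian
from skimage.registration import optical_flow_ilk

from .containers import FrameStack, StateLabels, TimeSeries

__all__ = [
    "DisplacementTrace",
    "register_frames",
    "interframe_stats",
    "whisker_flow",
    "whisk_frequency_distribution",
]


@dataclass
class DisplacementTrace:
    """Per-frame integer displacement relative to the average reference."""

    dx: np.ndarray          # px, NaN where excluded
    dy: np.ndarray
    excluded: np.ndarray    # bool
    reasons: list = field(default_factory=list)


def _roi_stack(frames: np.ndarray, roi: Tuple[int, int, int, int]) -> np.ndarray:
    x, y, w, h = roi
    if x < 0 or y < 0 or x + w > frames.shape[1] or y + h > frames.shape[0]:
        raise ValueError("ROI extends outside the frame")
    return frames[y:y + h, x:x + w, :].astype(float)


def _shift_window(frames: np.ndarray, roi, dx: int, dy: int) -> np.ndarray:
    x, y, w, h = roi
    return frames[y + dy:y + dy + h, x + dx:x + dx + w].astype(float)


def register_frames(
    stack: FrameStack,
    roi: Tuple[int, int, int, int],
    search_radius: int = 5,
    brightness_sd: float = 3.0,
) -> DisplacementTrace:
    """Register every frame's ROI against the average-reference ROI.

    ``roi`` = (x, y, w, h).  For each non-excluded frame the returned
    (dx, dy) maximizes the Pearson correlation between the reference
    (pixelwise mean ROI over non-excluded frames) and the frame window
    displaced by (dx, dy), over all integer shifts with
    |dx|, |dy| <= ``search_radius``.  Ties break toward the smaller
    shift magnitude, then lexicographically.

    Brightness exclusion is applied first: frames whose mean ROI
    brightness deviates more than ``brightness_sd`` standard deviations
    from the across-frame mean are excluded with reason ``"brightness"``.
    The reference is built in two passes (provisional mean → exclusions
    → final mean) so the exclusion rule and the averaging interact
    deterministically.
    """
    x, y, w, h = roi
    if search_radius >= min(w, h) / 2:
        raise ValueError("search radius must be smaller than half the ROI size")
    if stack.n_frames < 10:
        raise ValueError("need at least 10 frames for a stable reference")
    if (x - search_radius < 0 or y - search_radius < 0
            or x + w + search_radius > stack.frames.shape[1]
            or y + h + search_radius > stack.frames.shape[0]):
        raise ValueError("ROI plus search radius extends outside the frame")

    rois = _roi_stack(stack.frames, roi)
    n = stack.n_frames
    brightness = rois.mean(axis=(0, 1))
    sd = brightness.std()
    if sd > 0:
        excluded = np.abs(brightness - brightness.mean()) > brightness_sd * sd
    else:
        excluded = np.zeros(n, dtype=bool)
    reasons = ["brightness" if e else "" for e in excluded]

    reference = rois[:, :, ~excluded].mean(axis=2)
    ref_c = reference - reference.mean()
    ref_norm = np.sqrt((ref_c ** 2).sum())

    shifts = [
        (dx, dy)
        for dx in range(-search_radius, search_radius + 1)
        for dy in range(-search_radius, search_radius + 1)
    ]
    # stable tie-break: smaller magnitude first, then lexicographic
    shifts.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, s))

    dx_out = np.full(n, np.nan)
    dy_out = np.full(n, np.nan)
    for i in range(n):
        if excluded[i]:
            continue
        best, best_score = (0, 0), -np.inf
        for dx, dy in shifts:
            win = _shift_window(stack.frames[:, :, i], roi, dx, dy)
            win_c = win - win.mean()
            denom = ref_norm * np.sqrt((win_c ** 2).sum())
            score = (ref_c * win_c).sum() / denom if denom > 0 else -np.inf
            if score > best_score + 1e-12:
                best_score, best = score, (dx, dy)
        dx_out[i], dy_out[i] = best
    return DisplacementTrace(dx=dx_out, dy=dy_out, excluded=excluded, reasons=reasons)


def interframe_stats(
    disp: DisplacementTrace,
    pixel_pitch: float,
    covariate: Optional[np.ndarray] = None,
    bin_width: float = 2.0,
) -> Dict[str, np.ndarray]:
    """Inter-frame image movement statistics in µm.

    Movement per frame pair = Euclidean norm of the change in (dx, dy)
    between successive non-excluded frames, × ``pixel_pitch`` µm.
    Pairs spanning an excluded frame are dropped.  Returns the movement
    series, its cumulative distribution, and — when ``covariate`` (one
    value per frame, e.g. body speed or head acceleration) is given —
    covariate-binned means ± SEM with the configured ``bin_width``.
    """
    ok = ~disp.excluded
    valid_pair = ok[:-1] & ok[1:]
    if not np.any(valid_pair):
        raise ValueError("no consecutive non-excluded frame pairs")
    ddx = np.diff(disp.dx)[valid_pair]
    ddy = np.diff(disp.dy)[valid_pair]
    movement = np.hypot(ddx, ddy) * pixel_pitch
    sorted_m = np.sort(movement)
    cdf = np.arange(1, sorted_m.size + 1) / sorted_m.size
    out: Dict[str, np.ndarray] = {
        "movement_um": movement,
        "cdf_x": sorted_m,
        "cdf_y": cdf,
        "mean_um": np.array(movement.mean()),
    }
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)[1:][valid_pair]
        lo = np.floor(cov.min() / bin_width) * bin_width
        edges = np.arange(lo, cov.max() + bin_width, bin_width)
        if edges.size < 2:
            edges = np.array([lo, lo + bin_width])
        idx = np.digitize(cov, edges) - 1
        means, sems, centers = [], [], []
        for b in range(edges.size - 1):
            sel = idx == b
            if not sel.any():
                continue
            m = movement[sel]
            means.append(m.mean())
            sems.append(m.std(ddof=1) / np.sqrt(m.size) if m.size > 1 else 0.0)
            centers.append((edges[b] + edges[b + 1]) / 2)
        out["bin_centers"] = np.array(centers)
        out["bin_means"] = np.array(means)
        out["bin_sems"] = np.array(sems)
    return out


def whisker_flow(
    stack: FrameStack,
    roi: Tuple[int, int, int, int],
    radius: int = 7,
) -> TimeSeries:
    """Mean dense optical flow over a whisker-pad ROI, px/frame.

    One (h_flow, v_flow) pair per frame transition; h_flow relates to
    azimuthal, v_flow to elevational pad movement.  Times are the later
    frame of each pair.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rois = _roi_stack(stack.frames, roi)
    if rois.std() == 0:
        raise ValueError("ROI has zero variance; no texture to track")
    smoothed = [gaussian(rois[:, :, i], 2.0, preserve_range=True)
                for i in range(stack.n_frames)]
    h = np.empty(stack.n_frames - 1)
    v = np.empty(stack.n_frames - 1)
    for i in range(stack.n_frames - 1):
        fv, fu = optical_flow_ilk(smoothed[i], smoothed[i + 1], radius=radius)
        h[i] = fu.mean()
        v[i] = fv.mean()
    return TimeSeries(times=stack.timestamps[1:].copy(), values=np.vstack([h, v]),
                      units="px/frame", channel_names=["h_flow", "v_flow"])


def whisk_frequency_distribution(
    trace: TimeSeries,
    labels: StateLabels,
    window: float = 1.0,
    step: float = 0.5,
    min_prominence_ratio: float = 5.0,
    freq_range: Tuple[float, float] = (1.0, 25.0),
) -> Dict[str, np.ndarray]:
    """Dominant whisking frequency per sliding window, histogrammed by state.

    The spectral peak of the horizontal flow component is found per
    ``window``-second segment (step ``step`` s); windows whose peak
    power fails to exceed ``min_prominence_ratio`` × the median spectral
    power are treated as silent and contribute nothing.  Returns a dict
    mapping state name to the array of peak frequencies (Hz).
    """
    rate = 1.0 / float(np.median(np.diff(trace.times)))
    if rate < 2 * freq_range[1]:
        raise ValueError("frame rate below twice the analysis band")
    nwin = int(round(window * rate))
    nstep = max(int(round(step * rate)), 1)
    max_span = max((e - s) for s, e, _ in labels.intervals)
    if window > max_span:
        raise ValueError("window longer than every state segment")
    x = trace.values[0]
    out: Dict[str, list] = {}
    for start in range(0, x.size - nwin + 1, nstep):
        seg = x[start:start + nwin]
        mid_t = trace.times[start + nwin // 2]
        state = labels.state_at(float(mid_t))
        if state is None:
            continue
        freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
        power = np.abs(np.fft.rfft(seg - seg.mean())) ** 2
        band = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
        if not band.any() or power[band].max() <= 0:
            continue
        med = np.median(power[band])
        peak_i = np.argmax(power[band])
        if med > 0 and power[band][peak_i] < min_prominence_ratio * med:
            continue
        if med == 0 and power[band][peak_i] == 0:
            continue
        out.setdefault(state, []).append(freqs[band][peak_i])
    return {k: np.array(val) for k, val in out.items()}
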