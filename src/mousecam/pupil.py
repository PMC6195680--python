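"""Pupil detection from eye-facing camera frames.

Pipeline per frame: (1) mask contiguous bright corneal-reflection
regions and fill them by diffusion-style inpainting; (2) threshold the
dark pupil, extract its contour at subpixel resolution, and fit an
ellipse by least squares; (3) accept or reject the fit by mean-intensity
and area criteria.  Rejections carry a reason code instead of raising —
downstream analyses use only frames with a valid fit and never
interpolate across gaps.

Thresholds are per-session configuration (they were hand-tuned per
recording in practice); :func:`suggest_thresholds` offers an Otsu-based
starting point as a convenience only.

A separate optical-flow path estimates eye movements in the dark, where
the dilated pupil defeats ellipse fitting: the eye region is median
filtered, dense optical flow is averaged over pupil-edge pixels, and
the average flow is integrated over frames.  The integration is
leak-prone over long spans and is intended for initial movements after
an onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, median, threshold_otsu
from skimage.morphology import footprint_rectangle
from skimage.registration import optical_flow_ilk
from skimage.restoration import inpaint_biharmonic

from .containers import FrameStack, PupilFit, TimeSeries

__all__ = [
    "preprocess_eye_frame",
    "fit_pupil",
    "fit_pupil_stack",
    "smooth_pupil_trace",
    "SMOOTHING_KERNEL",
    "eye_flow_dark",
    "px_to_degrees",
    "pupil_trace",
    "suggest_thresholds",
]

# 3-point Gaussian used to smooth traces for display; analyses use raw fits.
SMOOTHING_KERNEL = np.array([0.072, 0.855, 0.072])

DEFAULT_PX_PER_DEG = 3.0


def preprocess_eye_frame(
    frame: np.ndarray, reflection_threshold: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Mask bright corneal reflections and inpaint them.

    Contiguous regions above ``reflection_threshold`` form a binary
    mask; masked pixels are replaced by smooth biharmonic inpainting
    from the boundary, unmasked pixels are untouched.

    Returns (inpainted uint8 frame, boolean mask).
    """
    frame = np.asarray(frame)
    if not 0 < reflection_threshold < 255:
        raise ValueError("reflection_threshold must be in (0, 255)")
    mask = frame > reflection_threshold
    if not mask.any():
        return frame.copy(), mask
    if mask.mean() > 0.5:
        raise ValueError("reflection mask covers more than half the frame; "
                         "likely occlusion or a wrong threshold")
    filled = inpaint_biharmonic(frame.astype(float), mask)
    out = frame.astype(float).copy()
    out[mask] = filled[mask]
    return np.clip(np.round(out), 0, 255).astype(np.uint8), mask


def fit_pupil(
    frame: np.ndarray,
    contour_threshold: float,
    max_mean_intensity: float = 255.0,
    min_area: float = 0.0,
    frame_index: int = 0,
    smooth_sigma: float = 1.0,
) -> PupilFit:
    """Fit an ellipse to the largest dark region of a preprocessed frame.

    The frame is lightly Gaussian-smoothed, thresholded at
    ``contour_threshold``, and the largest dark connected component's
    subpixel contour is fit by algebraic least squares.  Fits whose
    region mean intensity exceeds ``max_mean_intensity`` or whose
    ellipse area π·a·b/4 falls below ``min_area`` (px²) come back
    invalid with a reason code; no exception is raised for unfittable
    frames.
    """
    frame = np.asarray(frame, dtype=float)
    work = gaussian(frame, sigma=smooth_sigma, preserve_range=True) if smooth_sigma else frame
    dark = work < contour_threshold
    labeled, n_regions = ndimage.label(dark)
    if n_regions == 0:
        # nothing dark at all: an empty candidate trivially fails any
        # positive area criterion, otherwise there is just no contour
        reason = "area_below_min" if min_area > 0 else "no_contour"
        return PupilFit(frame_index=frame_index, reason=reason)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n_regions + 1))
    best = int(np.argmax(sizes)) + 1
    region = labeled == best

    # subpixel contour of the selected component only
    masked = np.where(region, work, contour_threshold + 1e3)
    contours = measure.find_contours(masked, level=contour_threshold)
    if not contours:
        return PupilFit(frame_index=frame_index, reason="no_contour")
    contour = max(contours, key=len)
    if contour.shape[0] < 5:
        return PupilFit(frame_index=frame_index, reason="no_contour")

    # EllipseModel expects (x, y); find_contours returns (row, col)
    model = measure.EllipseModel.from_estimate(contour[:, ::-1])
    if not model:
        return PupilFit(frame_index=frame_index, reason="fit_failed")
    xc, yc = model.center
    a, b = model.axis_lengths  # semi-axes, major first
    theta = model.theta
    major, minor = 2 * max(a, b), 2 * min(a, b)
    angle = np.rad2deg(theta) % 180.0
    if b > a:
        angle = (angle + 90.0) % 180.0

    mean_intensity = float(frame[region].mean())
    area = np.pi * major * minor / 4.0
    if area < min_area:
        return PupilFit(frame_index=frame_index, center_x=xc, center_y=yc,
                        mean_intensity=mean_intensity, reason="area_below_min")
    if mean_intensity > max_mean_intensity:
        return PupilFit(frame_index=frame_index, center_x=xc, center_y=yc,
                        mean_intensity=mean_intensity, reason="intensity_above_max")
    return PupilFit(frame_index=frame_index, center_x=float(xc), center_y=float(yc),
                    major_axis=float(major), minor_axis=float(minor),
                    angle=float(angle), mean_intensity=mean_intensity, valid=True)


def fit_pupil_stack(
    stack: FrameStack,
    reflection_threshold: Optional[float],
    contour_threshold: float,
    max_mean_intensity: float = 255.0,
    min_area: float = 0.0,
) -> List[PupilFit]:
    """Run reflection removal + ellipse fitting over a whole stack."""
    fits = []
    for i in range(stack.n_frames):
        frame = stack.frame(i)
        if reflection_threshold is not None:
            frame, _ = preprocess_eye_frame(frame, reflection_threshold)
        fits.append(fit_pupil(frame, contour_threshold, max_mean_intensity,
                              min_area, frame_index=i))
    return fits


def suggest_thresholds(frame: np.ndarray) -> dict:
    """Otsu-based starting points for the per-session thresholds.

    A convenience only — thresholds are session configuration and were
    selected by hand against a sample of frames in the original
    workflow.
    """
    otsu = float(threshold_otsu(np.asarray(frame)))
    return {
        "contour_threshold": otsu,
        "reflection_threshold": min(250.0, otsu + 0.8 * (255 - otsu)),
    }


def smooth_pupil_trace(values: np.ndarray, valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Smooth a pupil trace with the 3-tap kernel (0.072, 0.855, 0.072).

    For visualization only.  Gaps (invalid samples) are never bridged:
    each contiguous valid run is convolved separately, and runs shorter
    than 3 samples pass through unchanged.  Run endpoints keep their raw
    value (the kernel would otherwise leak mass off the run).
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    # contiguous runs of valid samples
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        if run.size < 3:
            continue
        seg = values[run]
        sm = np.convolve(seg, SMOOTHING_KERNEL, mode="same")
        sm[0], sm[-1] = seg[0], seg[-1]
        out[run] = sm
    return out


def _edge_pixels(frame: np.ndarray, rel_threshold: float = 0.25) -> np.ndarray:
    from skimage.filters import sobel

    grad = sobel(frame.astype(float))
    return grad >= rel_threshold * grad.max()


def eye_flow_dark(
    stack: FrameStack,
    eye_roi: Optional[Tuple[int, int, int, int]] = None,
    median_window: int = 15,
    edge_rel_threshold: float = 0.25,
    radius: int = 7,
) -> TimeSeries:
    """Integrated optical flow of the pupil edges: eye position in the dark.

    Each frame (optionally cropped to ``eye_roi`` = (x, y, w, h)) is
    median filtered with a ``median_window``-pixel square window so hair
    and LED reflections do not contaminate the flow; dense ILK optical
    flow between consecutive frames is averaged over pupil-edge pixels
    (strong-gradient pixels of the first frame of the pair) and summed
    over time.  Position is relative to the first frame, in px.

    The estimate is documented as leak-prone: integration error can
    accumulate over long spans, so use it for initial movements after
    an onset.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = stack.frames
    if eye_roi is not None:
        x, y, w, h = eye_roi
        if x < 0 or y < 0 or x + w > frames.shape[1] or y + h > frames.shape[0]:
            raise ValueError("ROI extends outside the frame")
        frames = frames[y:y + h, x:x + w, :]
    foot = footprint_rectangle((median_window, median_window))
    # median kills speckle (hair, LED glints); the Gaussian regularizes the
    # step edges of the pupil so the local least-squares flow stays stable
    filt = [
        gaussian(median(frames[:, :, i], footprint=foot).astype(float), 2.0,
                 preserve_range=True)
        for i in range(frames.shape[2])
    ]
    disp = np.zeros((2, stack.n_frames))  # (x, y), px, relative to frame 0
    for i in range(stack.n_frames - 1):
        ref, mov = filt[i].astype(float), filt[i + 1].astype(float)
        edges = _edge_pixels(ref, edge_rel_threshold)
        if not edges.any():
            raise ValueError(f"no edge pixels in frame {i}")
        # returned flow is the content displacement (row, col) from ref to mov
        v, u = optical_flow_ilk(ref, mov, radius=radius)
        disp[0, i + 1] = disp[0, i] + u[edges].mean()
        disp[1, i + 1] = disp[1, i] + v[edges].mean()
    return TimeSeries(times=stack.timestamps.copy(), values=disp,
                      units="px", channel_names=["x", "y"])


def px_to_degrees(trace: TimeSeries, deg_per_px: float = 1.0 / DEFAULT_PX_PER_DEG) -> TimeSeries:
    """Convert a pixel-valued eye trace to degrees by linear scaling."""
    if not deg_per_px > 0:
        raise ValueError("scale must be > 0")
    out = trace.copy_with(values=trace.values * deg_per_px, units="deg")
    return out


def pupil_trace(
    fits: List[PupilFit],
    timestamps: np.ndarray,
    deg_per_px: float = 1.0 / DEFAULT_PX_PER_DEG,
    origin: Optional[Tuple[float, float]] = None,
) -> TimeSeries:
    """Assemble valid pupil fits into an eye-position trace (degrees).

    Only frames with a valid fit appear — gaps are absent samples, never
    interpolated.  ``origin`` (px) defaults to the mean fitted center;
    vertical is sign-flipped so up is positive.  Pupil diameter (major
    axis, px) rides along as a third channel.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    ok = [f for f in fits if f.valid]
    if not ok:
        raise ValueError("no valid pupil fits")
    t = np.array([timestamps[f.frame_index] for f in ok])
    cx = np.array([f.center_x for f in ok])
    cy = np.array([f.center_y for f in ok])
    diam = np.array([f.major_axis for f in ok])
    if origin is None:
        origin = (float(cx.mean()), float(cy.mean()))
    horiz = (cx - origin[0]) * deg_per_px
    vert = -(cy - origin[1]) * deg_per_px
    return TimeSeries(times=t, values=np.vstack([horiz, vert, diam]),
                      units="deg", channel_names=["horizontal", "vertical", "diameter_px"])
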