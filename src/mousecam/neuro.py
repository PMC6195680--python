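"""Neural-signal analyses tied to behavior.

Covers recording-quality spectra (Welch PSD and camera-on/off PSD
ratio), spike SNR against the inter-spike noise floor, LFP band power
(2–10 Hz and 10–20 Hz), pupil–LFP correlation during head-still
segments, event-aligned rasters/averages, and the event-aligned
modulation index

    MI = (Npost − Npre) / (Npost + Npre)

with Npre/Npost the average spike counts in the 1 s windows before and
after movement onset (no baseline subtraction), tested per cell by a
Wilcoxon signed-rank on the per-event (pre, post) count pairs.

Head-movement onsets can further be split by whether the accompanying
eye movement matched the head-orientation model's prediction (cosine
similarity of the initial eye-movement vectors ≥ 0.5) to ask whether
gaze-stabilizing and other eye movements modulate firing differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import wilcoxon

from .containers import EventTable, SpikeTrain, TimeSeries

__all__ = [
    "welch_psd",
    "psd_ratio",
    "segment_psd_ratio_sd",
    "spike_snr",
    "lfp_band_power",
    "find_still_segments",
    "pupil_lfp_correlation",
    "align_spikes",
    "align_trace",
    "Raster",
    "MIResult",
    "modulation_index",
    "split_by_eye_predictability",
]


def welch_psd(
    x: np.ndarray, fs: float, window: float = 2.0, overlap: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Welch PSD with a 2 s Hann window and 1 s overlap (defaults).

    Density-normalized: the integral over frequency approximates the
    signal variance.  Returns (freqs, psd).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one window")
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=int(round(overlap * fs)))
    return freqs, psd


def psd_ratio(psd_a, psd_b, freqs_a=None, freqs_b=None) -> np.ndarray:
    """Elementwise PSD ratio a/b; zero-denominator bins come back NaN."""
    psd_a = np.asarray(psd_a, dtype=float)
    psd_b = np.asarray(psd_b, dtype=float)
    if psd_a.shape != psd_b.shape:
        raise ValueError("PSDs must share a frequency axis")
    if freqs_a is not None and freqs_b is not None and not np.allclose(freqs_a, freqs_b):
        raise ValueError("frequency axes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(psd_b > 0, psd_a / np.where(psd_b > 0, psd_b, 1.0), np.nan)
    return ratio


def segment_psd_ratio_sd(
    x_a: np.ndarray, x_b: np.ndarray, fs: float, segment: float = 60.0,
    window: float = 2.0, overlap: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-condition variability of the PSD ratio.

    Both signals are cut into non-overlapping ``segment``-second pieces;
    the per-segment PSD ratio is computed and its SD across segments
    returned.  Returns (freqs, mean_ratio, sd_ratio).
    """
    nseg = int(round(segment * fs))
    n = min(len(x_a), len(x_b)) // nseg
    if n < 2:
        raise ValueError("need at least 2 non-overlapping segments")
    ratios = []
    for i in range(n):
        sl = slice(i * nseg, (i + 1) * nseg)
        f, pa = welch_psd(x_a[sl], fs, window, overlap)
        _, pb = welch_psd(x_b[sl], fs, window, overlap)
        ratios.append(psd_ratio(pa, pb))
    ratios = np.asarray(ratios)
    return f, np.nanmean(ratios, axis=0), np.nanstd(ratios, axis=0, ddof=1)


def spike_snr(
    trace: np.ndarray,
    fs: float,
    spike_times: np.ndarray,
    margin: float = 0.002,
    spike_halfwidth: float = 0.001,
) -> float:
    """SNR of spike waveforms against the inter-spike noise floor.

    Signal power is the mean square of the high-passed trace within
    ±``spike_halfwidth`` of each spike; noise power is the mean square
    over samples at least ``margin`` (2 ms default) away from every
    spike.
    """
    trace = np.asarray(trace, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    n = trace.size
    idx = np.round(spike_times * fs).astype(int)
    half = int(round(spike_halfwidth * fs))
    marg = int(round(margin * fs))
    if np.any(idx - half < 0) or np.any(idx + half >= n):
        raise ValueError("spike windows must lie inside the trace")
    spike_mask = np.zeros(n, dtype=bool)
    noise_excl = np.zeros(n, dtype=bool)
    for i in idx:
        spike_mask[i - half:i + half + 1] = True
        noise_excl[max(i - marg, 0):i + marg + 1] = True
    if not np.any(~noise_excl):
        raise ValueError("no inter-spike samples remain after margin exclusion")
    sig_power = np.mean(trace[spike_mask] ** 2)
    noise_power = np.mean(trace[~noise_excl] ** 2)
    return float(sig_power / noise_power)


def lfp_band_power(
    lfp: TimeSeries,
    band: Tuple[float, float] = (2.0, 10.0),
    smooth_sd: float = 2.0,
    order: int = 4,
    quiescent_mask: Optional[np.ndarray] = None,
    normalize: bool = False,
) -> TimeSeries:
    """Time-resolved LFP band power.

    Zero-phase 4th-order Butterworth bandpass → squaring → Gaussian
    smoothing (SD ``smooth_sd`` s).  With ``normalize=True`` the trace
    is divided by the mean power over ``quiescent_mask`` (all samples
    when no mask is given), so mean quiescent low-band power is 1.
    """
    rate = lfp.rate or 1.0 / float(np.median(np.diff(lfp.times)))
    if band[1] >= rate / 2:
        raise ValueError("band edge at or above Nyquist")
    b, a = sps.butter(order, band, btype="band", fs=rate)
    power = sps.filtfilt(b, a, lfp.values[0]) ** 2
    if smooth_sd > 0:
        power = gaussian_filter1d(power, smooth_sd * rate)
    if normalize:
        ref = power if quiescent_mask is None else power[np.asarray(quiescent_mask, bool)]
        power = power / ref.mean()
    return TimeSeries(times=lfp.times.copy(), values=power, rate=lfp.rate,
                      units="norm" if normalize else "power",
                      channel_names=[f"power_{band[0]:g}-{band[1]:g}Hz"])


def find_still_segments(
    head_mag: TimeSeries, still_thr: float = 0.02, min_duration: float = 15.0
) -> np.ndarray:
    """Intervals (start, end) where head-movement magnitude stays below
    ``still_thr`` g for at least ``min_duration`` s (default 15 s)."""
    below = head_mag.values[0] < still_thr
    t = head_mag.times
    edges = np.diff(below.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)
    out = [
        (t[s], t[e - 1]) for s, e in zip(starts, ends)
        if t[e - 1] - t[s] >= min_duration
    ]
    return np.array(out).reshape(-1, 2)


def pupil_lfp_correlation(
    band_power: TimeSeries,
    pupil_diameter: TimeSeries,
    head_mag: TimeSeries,
    still_thr: float = 0.02,
    min_still: float = 15.0,
    n_shuffle: int = 1000,
    min_shift: float = 5.0,
    seed: int = 0,
) -> dict:
    """Pupil-diameter vs LFP-power correlation during head-still segments.

    Segments where the head stays still for at least ``min_still`` s
    are found from the movement magnitude; within each, the Pearson
    correlation between pupil diameter and band power is computed.  The
    null circularly shifts the pupil trace within the segment by at
    least ``min_shift`` s, ``n_shuffle`` draws pooled over segments.
    """
    segments = find_still_segments(head_mag, still_thr, min_still)
    if segments.size == 0:
        warnings.warn("no head-still segment of sufficient duration")
        return {"cc": np.array([]), "null": np.array([]), "segments": segments}
    rng = np.random.default_rng(seed)
    ccs, null = [], []
    for t0, t1 in segments:
        sel = (band_power.times >= t0) & (band_power.times <= t1)
        bp = band_power.values[0, sel]
        pup = np.interp(band_power.times[sel], pupil_diameter.times,
                        pupil_diameter.values[0])
        if bp.size < 3 or bp.std() == 0 or pup.std() == 0:
            continue
        ccs.append(float(np.corrcoef(bp, pup)[0, 1]))
        rate = 1.0 / float(np.median(np.diff(band_power.times[sel])))
        min_k = int(round(min_shift * rate))
        if bp.size > 2 * min_k:
            shifts = rng.integers(min_k, bp.size - min_k, size=n_shuffle)
            for k in shifts:
                null.append(float(np.corrcoef(bp, np.roll(pup, k))[0, 1]))
    return {"cc": np.array(ccs), "null": np.array(null), "segments": segments}


# ---------------------------------------------------------------------------
# Event alignment, rasters, modulation index


@dataclass
class Raster:
    """Event-aligned spike counts: events × time bins."""

    counts: np.ndarray
    bin_edges: np.ndarray       # relative to event, s
    event_times: np.ndarray
    n_dropped: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def psth(self) -> Tuple[np.ndarray, np.ndarray]:
        """Mean rate (Hz) per bin and its SEM across events."""
        width = np.diff(self.bin_edges)
        rates = self.counts / width
        return rates.mean(axis=0), rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0])


def align_spikes(
    spikes: SpikeTrain,
    events: EventTable,
    window: Tuple[float, float] = (-1.0, 1.0),
    bin_width: float = 0.05,
    recording_span: Optional[Tuple[float, float]] = None,
) -> Raster:
    """Stack spike counts around each event into a raster.

    Events whose window leaves ``recording_span`` (defaults to the span
    of the spike train) are dropped and counted in ``n_dropped``.
    """
    t_pre, t_post = window
    edges = np.arange(t_pre, t_post + bin_width / 2, bin_width)
    if recording_span is None:
        recording_span = (float(spikes.spike_times.min(initial=0.0)),
                          float(spikes.spike_times.max(initial=0.0)))
    usable, rows = [], []
    for t0 in events.times:
        if t0 + t_pre < recording_span[0] or t0 + t_post > recording_span[1]:
            continue
        rel = spikes.spike_times - t0
        rows.append(np.histogram(rel, bins=edges)[0])
        usable.append(t0)
    if not rows:
        raise ValueError("no events with a full window inside the recording")
    return Raster(counts=np.asarray(rows), bin_edges=edges,
                  event_times=np.asarray(usable),
                  n_dropped=len(events) - len(usable))


def align_trace(
    trace: TimeSeries,
    events: EventTable,
    window: Tuple[float, float] = (-1.0, 1.0),
    channel: int = 0,
) -> dict:
    """Event-aligned average of a continuous trace with SEM.

    Events whose window leaves the recording are dropped (count
    reported).  Returns lags, the aligned matrix, mean, and SEM.
    """
    t_pre, t_post = window
    dt = 1.0 / (trace.rate or 1.0 / float(np.median(np.diff(trace.times))))
    lags = np.arange(t_pre, t_post + dt / 2, dt)
    rows, used = [], []
    for t0 in events.times:
        if t0 + t_pre < trace.times[0] or t0 + t_post > trace.times[-1]:
            continue
        rows.append(np.interp(t0 + lags, trace.times, trace.values[channel]))
        used.append(t0)
    if not rows:
        raise ValueError("no events with a full window inside the recording")
    rows = np.asarray(rows)
    return {"lags": lags, "aligned": rows, "mean": rows.mean(axis=0),
            "sem": rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0]),
            "n_dropped": len(events) - len(used)}


@dataclass
class MIResult:
    """Event-aligned modulation index with Wilcoxon signed-rank p-value."""

    mi: float
    n_pre: float
    n_post: float
    p: float
    defined: bool = True


def modulation_index(
    spikes: SpikeTrain,
    events: EventTable,
    pre: float = 1.0,
    post: float = 1.0,
    recording_span: Optional[Tuple[float, float]] = None,
) -> MIResult:
    """MI = (Npost − Npre)/(Npost + Npre) from exact window spike counts.

    Npre and Npost are the average counts in the ``pre`` s before and
    ``post`` s after each event (no baseline subtraction, no binning);
    p comes from a Wilcoxon signed-rank on the per-event (pre, post)
    pairs (zero-difference pairs dropped; exact distribution for small
    n per scipy's policy).
    """
    if recording_span is None:
        recording_span = (float(spikes.spike_times.min(initial=0.0)),
                          float(spikes.spike_times.max(initial=0.0)))
    pre_counts, post_counts = [], []
    for t0 in events.times:
        if t0 - pre < recording_span[0] or t0 + post > recording_span[1]:
            continue
        st = spikes.spike_times
        pre_counts.append(np.sum((st >= t0 - pre) & (st < t0)))
        post_counts.append(np.sum((st > t0) & (st <= t0 + post)))
    if not pre_counts:
        raise ValueError("no events with a full window inside the recording")
    pre_counts = np.asarray(pre_counts, dtype=float)
    post_counts = np.asarray(post_counts, dtype=float)
    n_pre, n_post = pre_counts.mean(), post_counts.mean()
    denom = n_pre + n_post
    if denom == 0:
        return MIResult(mi=np.nan, n_pre=0.0, n_post=0.0, p=np.nan, defined=False)
    mi = (n_post - n_pre) / denom
    diffs = post_counts - pre_counts
    if np.all(diffs == 0):
        p = 1.0
    else:
        p = float(wilcoxon(pre_counts, post_counts).pvalue)
    return MIResult(mi=float(mi), n_pre=float(n_pre), n_post=float(n_post), p=p)


def _earliest_extremum(t: np.ndarray, xy: np.ndarray, t0: float,
                       search: float) -> Optional[np.ndarray]:
    """Earliest strict local extremum of either displacement component in
    (t0, t0 + search]; returns the displacement vector at that time."""
    sel = (t > t0) & (t <= t0 + search)
    idx = np.flatnonzero(sel)
    if idx.size < 1:
        return None
    ref = np.array([np.interp(t0, t, xy[0]), np.interp(t0, t, xy[1])])
    best_i = None
    for i in idx:
        if i == 0 or i == t.size - 1:
            continue
        for c in range(2):
            a, b, cc = xy[c, i - 1], xy[c, i], xy[c, i + 1]
            if (b > a and b > cc) or (b < a and b < cc):
                best_i = i
                break
        if best_i is not None:
            break
    if best_i is None:
        return None
    return xy[:, best_i] - ref


def split_by_eye_predictability(
    onsets: EventTable,
    measured_eye: TimeSeries,
    predicted_eye: TimeSeries,
    cos_thr: float = 0.5,
    search: float = 0.100,
) -> Tuple[EventTable, EventTable, int]:
    """Split movement onsets by how well the eye movement matched prediction.

    For each onset, the initial eye movement is the displacement vector
    at the earliest peak/trough within ``search`` s after the onset, in
    both the measured and the model-predicted trace.  Onsets without an
    extremum in-window in either trace, or with a zero-length vector,
    are excluded (count returned).  Onsets with cosine similarity ≥
    ``cos_thr`` go to the "predictable" table, the rest to "other".
    """
    pred_times, other_times, excluded = [], [], 0
    for t0 in onsets.times:
        vm = _earliest_extremum(measured_eye.times, measured_eye.values[:2], t0, search)
        vp = _earliest_extremum(predicted_eye.times, predicted_eye.values[:2], t0, search)
        if vm is None or vp is None:
            excluded += 1
            continue
        nm, npd = np.linalg.norm(vm), np.linalg.norm(vp)
        if nm == 0 or npd == 0:
            excluded += 1
            continue
        cos = float(vm @ vp / (nm * npd))
        (pred_times if cos >= cos_thr else other_times).append(t0)
    return (
        EventTable(times=np.array(pred_times), labels=["predictable"] * len(pred_times)),
        EventTable(times=np.array(other_times), labels=["other"] * len(other_times)),
        excluded,
    )
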