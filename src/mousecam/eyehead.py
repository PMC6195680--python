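"""Predictive models of eye position from head orientation.

In freely moving mice, eye position is strongly coupled to head
orientation: pitching the nose down rotates the eyes upward, rolling
the head rotates them counter-rolling, consistent with vestibulo-ocular
and otolith-driven reflexes.  The core model is a lagged linear
regression

    p_i = k_pitch' u_i + k_roll' v_i (+ k_yaw' w_i) + k0 + N(0, σ²)

where u_i, v_i (w_i) hold the head pitch/roll (and leaky-integrated
yaw) history at lags −500…0 ms in 25 ms steps (21 lags per signal),
linearly interpolated onto the lag grid.  Weights are fit by automatic
relevance determination (ARD, evidence maximization with
per-coefficient precisions), which shrinks irrelevant lags; a
one-hidden-layer MLP regressor probes for nonlinear structure.
Performance is pooled R² = 1 − rss/tss on held-out data from
contiguous-block k-fold cross-validation (blocks, because temporal
autocorrelation would let random splits leak).

Saccade-like eye movements are local maxima of eye speed above 250 °/s;
their timing relative to head movements, and the velocity coupling of
eye to head rotation, are analyzed here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.linear_model import ARDRegression
from sklearn.neural_network import MLPRegressor

from .containers import EventTable, TimeSeries
from .imu import detect_onsets
from .synthetic import LAG_GRID_S, N_LAGS

__all__ = [
    "LaggedDesign",
    "EyeHeadModel",
    "FitReport",
    "SaccadeEvent",
    "build_lagged_design",
    "fit_linear_ard",
    "fit_nonlinear",
    "crossval_r2",
    "interocular_error_correlation",
    "eye_speed",
    "detect_saccades",
    "saccade_head_timing",
    "eye_head_velocity_coupling",
]


@dataclass
class LaggedDesign:
    """Time-lagged head-orientation design matrix for one eye axis.

    ``X`` has 21 columns per head signal (lags −500…0 ms step 25 ms) in
    signal blocks ordered as ``signals``; ``y`` is the eye position (°)
    at each row's sample time.
    """

    X: np.ndarray
    y: np.ndarray
    times: np.ndarray
    signals: Tuple[str, ...] = ("pitch", "roll")

    def __post_init__(self):
        if self.X.shape[1] != N_LAGS * len(self.signals):
            raise ValueError(
                f"design has {self.X.shape[1]} columns; expected "
                f"{N_LAGS} × {len(self.signals)} signals"
            )

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def block(self, signal: str) -> np.ndarray:
        i = self.signals.index(signal)
        return self.X[:, i * N_LAGS:(i + 1) * N_LAGS]


@dataclass
class EyeHeadModel:
    """Fitted eye-head model: per-lag weight vectors, offset, residual variance."""

    kind: str  # "linear-ard" or "nonlinear"
    k_pitch: Optional[np.ndarray] = None
    k_roll: Optional[np.ndarray] = None
    k_yaw: Optional[np.ndarray] = None
    k0: float = 0.0
    sigma2: float = 0.0
    regressor: object = None
    signals: Tuple[str, ...] = ("pitch", "roll")

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "linear-ard":
            return self.regressor.predict(X)
        return self.regressor.predict(X)

    @property
    def weights(self) -> np.ndarray:
        parts = [w for w in (self.k_pitch, self.k_roll, self.k_yaw) if w is not None]
        return np.concatenate(parts)


@dataclass
class FitReport:
    """Cross-validation report: pooled and per-fold R², rss/tss bookkeeping."""

    r2: float
    rss: float
    tss: float
    fold_r2: List[float] = field(default_factory=list)

    def __post_init__(self):
        if self.tss > 0:
            assert abs(self.r2 - (1 - self.rss / self.tss)) < 1e-9


def build_lagged_design(
    head: TimeSeries,
    eye: TimeSeries,
    eye_channel: int = 0,
    window: float = 0.5,
    step: float = 0.025,
) -> LaggedDesign:
    """Interpolate head signals onto the lag grid for every eye sample.

    Head channels (pitch, roll, and optionally a yaw-position channel)
    are linearly interpolated at each eye sample time plus each lag in
    −``window``…0 s (step ``step``).  Eye samples whose 500 ms history
    leaves the recorded head span are dropped.
    """
    lags = np.arange(-window, 0.0 + 1e-9, step)
    t_eye = eye.times
    ok = (t_eye + lags[0] >= head.times[0]) & (t_eye <= head.times[-1])
    if not np.any(ok):
        raise ValueError("no overlap between head and eye recordings")
    t_eye = t_eye[ok]
    y = eye.values[eye_channel, ok]
    blocks = []
    for ch in range(head.n_channels):
        sig = head.values[ch]
        cols = [np.interp(t_eye + lag, head.times, sig) for lag in lags]
        blocks.append(np.column_stack(cols))
    names = tuple(head.channel_names) if head.channel_names else tuple(
        f"signal{i}" for i in range(head.n_channels)
    )
    return LaggedDesign(X=np.hstack(blocks), y=y, times=t_eye, signals=names)


def _model_from_linear(reg: ARDRegression, design: LaggedDesign) -> EyeHeadModel:
    coef = reg.coef_
    parts = {s: coef[i * N_LAGS:(i + 1) * N_LAGS] for i, s in enumerate(design.signals)}
    return EyeHeadModel(
        kind="linear-ard",
        k_pitch=parts.get("pitch"),
        k_roll=parts.get("roll"),
        k_yaw=parts.get("yaw"),
        k0=float(reg.intercept_),
        sigma2=float(1.0 / reg.alpha_),
        regressor=reg,
        signals=design.signals,
    )


def fit_linear_ard(design: LaggedDesign, max_iter: int = 1000,
                   tol: float = 1e-8) -> Tuple[EyeHeadModel, FitReport]:
    """Fit the lagged linear model by automatic relevance determination.

    Evidence maximization with one precision hyperparameter per
    coefficient; irrelevant lags are shrunk toward zero (soft shrinkage
    only — no hard pruning, so a noiseless, identifiable design is
    recovered to numerical precision).  Deterministic given the data.
    The report's R² is in-sample; use :func:`crossval_r2` for the
    held-out figure.
    """
    if design.n_rows < 10 * design.X.shape[1]:
        warnings.warn("fewer than 10 rows per column; ARD fit may be unstable")
    reg = ARDRegression(max_iter=max_iter, tol=tol, threshold_lambda=1e12)
    reg.fit(design.X, design.y)
    model = _model_from_linear(reg, design)
    pred = reg.predict(design.X)
    rss = float(np.sum((design.y - pred) ** 2))
    tss = float(np.sum((design.y - design.y.mean()) ** 2))
    return model, FitReport(r2=1 - rss / tss, rss=rss, tss=tss)


def fit_nonlinear(design: LaggedDesign, seed: int = 0, hidden_units: int = 100,
                  max_iter: int = 500) -> Tuple[EyeHeadModel, FitReport]:
    """Fit the nonlinear eye-head model: MLP with 100 rectified-linear units."""
    reg = MLPRegressor(hidden_layer_sizes=(hidden_units,), activation="relu",
                       solver="adam", random_state=seed, max_iter=max_iter)
    reg.fit(design.X, design.y)
    pred = reg.predict(design.X)
    rss = float(np.sum((design.y - pred) ** 2))
    tss = float(np.sum((design.y - design.y.mean()) ** 2))
    model = EyeHeadModel(kind="nonlinear", regressor=reg, signals=design.signals,
                         sigma2=rss / max(design.n_rows, 1))
    return model, FitReport(r2=1 - rss / tss, rss=rss, tss=tss)


def crossval_r2(
    fitter: Callable[[LaggedDesign], Tuple[EyeHeadModel, FitReport]],
    design: LaggedDesign,
    k: int = 5,
) -> FitReport:
    """Pooled k-fold cross-validated R² with contiguous-block folds.

    R² is computed once on the concatenated held-out predictions
    (1 − rss/tss with tss about the pooled held-out mean), so folds
    with little variance cannot blow up the average.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = design.n_rows
    bounds = np.linspace(0, n, k + 1).astype(int)
    if np.any(np.diff(bounds) < 2):
        raise ValueError("a fold has fewer than 2 samples")
    preds = np.empty(n)
    fold_r2 = []
    for f in range(k):
        test = np.zeros(n, dtype=bool)
        test[bounds[f]:bounds[f + 1]] = True
        sub = LaggedDesign(X=design.X[~test], y=design.y[~test],
                           times=design.times[~test], signals=design.signals)
        model, _ = fitter(sub)
        p = model.predict(design.X[test])
        preds[test] = p
        rss_f = np.sum((design.y[test] - p) ** 2)
        tss_f = np.sum((design.y[test] - design.y[test].mean()) ** 2)
        fold_r2.append(1 - rss_f / tss_f if tss_f > 0 else np.nan)
    rss = float(np.sum((design.y - preds) ** 2))
    tss = float(np.sum((design.y - design.y.mean()) ** 2))
    return FitReport(r2=1 - rss / tss, rss=rss, tss=tss, fold_r2=fold_r2)


def interocular_error_correlation(
    left_y: np.ndarray, left_pred: np.ndarray,
    right_y: np.ndarray, right_pred: np.ndarray,
    min_samples: int = 30,
) -> float:
    """Pearson correlation between the two eyes' model residuals (one axis).

    High residual correlation means the eyes move together in ways the
    head-orientation model does not explain (conjugate saccades);
    residuals must come from simultaneous valid samples.
    """
    res_l = np.asarray(left_y) - np.asarray(left_pred)
    res_r = np.asarray(right_y) - np.asarray(right_pred)
    if res_l.size != res_r.size:
        raise ValueError("residual vectors must be paired samples")
    if res_l.size < min_samples:
        raise ValueError(f"need at least {min_samples} joint samples")
    return float(np.corrcoef(res_l, res_r)[0, 1])


# ---------------------------------------------------------------------------
# Saccades and velocity coupling


@dataclass
class SaccadeEvent:
    """One saccade-like eye movement (peak eye speed above threshold)."""

    peak_time: float
    peak_speed: float
    dh: float
    dv: float
    context: str  # "head-still" or "head-moving"


def eye_speed(eye: TimeSeries, max_gap: Optional[float] = None) -> TimeSeries:
    """Eye speed (°/s) by central differences within contiguous valid runs.

    Samples separated by more than ``max_gap`` (default 2.5× the median
    step) start a new run; speed is never differentiated across a gap.
    """
    t = eye.times
    h, v = eye.values[0], eye.values[1]
    if max_gap is None:
        max_gap = 2.5 * float(np.median(np.diff(t)))
    speed = np.full(t.size, np.nan)
    run_start = 0
    breaks = np.flatnonzero(np.diff(t) > max_gap) + 1
    for run in np.split(np.arange(t.size), breaks):
        if run.size < 2:
            continue
        vh = np.gradient(h[run], t[run])
        vv = np.gradient(v[run], t[run])
        speed[run] = np.hypot(vh, vv)
    return TimeSeries(times=t.copy(), values=speed, units="deg/s",
                      channel_names=["speed"])


def detect_saccades(
    eye: TimeSeries,
    head_mag: Optional[TimeSeries] = None,
    speed_thr: float = 250.0,
    head_thr: float = 0.0625,
    disp_halfwin: float = 0.020,
) -> List[SaccadeEvent]:
    """Detect saccade-like eye movements as eye-speed peaks above threshold.

    A sample is a peak when its speed exceeds ``speed_thr`` °/s, is not
    below its predecessor, and strictly exceeds its successor (ties
    break to the earlier sample).  Displacement (dh, dv) spans 20 ms
    before to 20 ms after the peak.  Context is "head-still" when the
    head-movement magnitude at the peak is below ``head_thr`` g.
    """
    sp = eye_speed(eye)
    s = sp.values[0]
    t = sp.times
    events = []
    for i in range(1, t.size - 1):
        if not np.isfinite(s[i]) or s[i] <= speed_thr:
            continue
        left = s[i - 1] if np.isfinite(s[i - 1]) else -np.inf
        right = s[i + 1] if np.isfinite(s[i + 1]) else -np.inf
        if s[i] >= left and s[i] > right:
            dh = float(np.interp(t[i] + disp_halfwin, eye.times, eye.values[0])
                       - np.interp(t[i] - disp_halfwin, eye.times, eye.values[0]))
            dv = float(np.interp(t[i] + disp_halfwin, eye.times, eye.values[1])
                       - np.interp(t[i] - disp_halfwin, eye.times, eye.values[1]))
            context = "head-still"
            if head_mag is not None:
                m = float(np.interp(t[i], head_mag.times, head_mag.values[0]))
                if m >= head_thr:
                    context = "head-moving"
            events.append(SaccadeEvent(peak_time=float(t[i]), peak_speed=float(s[i]),
                                       dh=dh, dv=dv, context=context))
    return events


def _gaps_to_moves(times: np.ndarray, intervals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per event: time since preceding movement offset, time to next onset."""
    offsets = intervals[:, 1]
    onsets = intervals[:, 0]
    prev = np.full(times.size, np.nan)
    nxt = np.full(times.size, np.nan)
    for i, t in enumerate(times):
        before = offsets[offsets <= t]
        after = onsets[onsets >= t]
        if before.size:
            prev[i] = t - before.max()
        if after.size:
            nxt[i] = after.min() - t
    return prev, nxt


def saccade_head_timing(
    saccade_times: np.ndarray,
    head_move_intervals: np.ndarray,
    still_intervals: np.ndarray,
    n_sim: int = 100,
    seed: int = 0,
    min_saccades: int = 10,
) -> dict:
    """Compare saccade timing relative to head movements against chance.

    For each head-still saccade the gap to the preceding head-movement
    offset and to the subsequent onset is computed.  The null keeps the
    saccade count but places events uniformly at random within the
    head-still intervals, ``n_sim`` times.  The statistic is the
    two-sample KS distance between the empirical preceding-gap
    distribution and the pooled null; p is Monte Carlo, comparing the
    observed KS with each simulation's KS against the same pooled null.
    """
    saccade_times = np.asarray(saccade_times, dtype=float)
    head_move_intervals = np.atleast_2d(np.asarray(head_move_intervals, dtype=float))
    still = np.atleast_2d(np.asarray(still_intervals, dtype=float))
    if saccade_times.size == 0:
        raise ValueError("empty saccade list")
    if saccade_times.size < min_saccades:
        raise ValueError(f"need at least {min_saccades} head-still saccades")
    durs = still[:, 1] - still[:, 0]
    if not np.any(durs > 0):
        raise ValueError("no head-still time available")
    rng = np.random.default_rng(seed)

    prev_obs, _ = _gaps_to_moves(saccade_times, head_move_intervals)
    prev_obs = prev_obs[np.isfinite(prev_obs)]

    def draw() -> np.ndarray:
        seg = rng.choice(durs.size, size=saccade_times.size, p=durs / durs.sum())
        t = still[seg, 0] + rng.uniform(0, 1, saccade_times.size) * durs[seg]
        prev, _ = _gaps_to_moves(np.sort(t), head_move_intervals)
        return prev[np.isfinite(prev)]

    sims = [draw() for _ in range(n_sim)]
    pooled = np.concatenate(sims)
    ks_obs = stats.ks_2samp(prev_obs, pooled).statistic
    ks_null = np.array([stats.ks_2samp(s, pooled).statistic for s in sims])
    p = (np.sum(ks_null >= ks_obs) + 1) / (n_sim + 1)
    return {"gaps": prev_obs, "null_gaps": pooled, "ks": float(ks_obs),
            "ks_null": ks_null, "p": float(p)}


def eye_head_velocity_coupling(
    eye_velocity: TimeSeries,
    head_velocity: TimeSeries,
    bin_width: float = 10.0,
    onset_speed_thr: float = 15.0,
    onset_pre: float = 0.5,
    onset_post: float = 0.1,
    align_window: float = 1.0,
) -> dict:
    """Eye-vs-head velocity tuning, rotation-onset averages, cross-correlation.

    Head angular velocity (yaw, °/s) is binned at ``bin_width`` and the
    mean ± SEM of the simultaneous horizontal eye velocity reported per
    bin, with the least-squares slope (compensatory eye movements give
    a negative slope).  Rotational-movement onsets (speed ≥ 15 °/s with
    0.5 s of stillness before) are detected with the shared onset rule
    and the onset-aligned mean eye velocity returned; the normalized
    cross-correlation of the two velocity traces is reported with its
    lag axis.
    """
    he = np.interp(eye_velocity.times, head_velocity.times, head_velocity.values[0])
    ev = eye_velocity.values[0]
    ok = np.isfinite(ev) & np.isfinite(he)
    he, ev_ok = he[ok], ev[ok]
    lo = np.floor(he.min() / bin_width) * bin_width
    edges = np.arange(lo, he.max() + bin_width, bin_width)
    idx = np.digitize(he, edges) - 1
    centers, means, sems = [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.sum() < 2:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2)
        means.append(ev_ok[sel].mean())
        sems.append(ev_ok[sel].std(ddof=1) / np.sqrt(sel.sum()))
    slope, intercept = np.polyfit(he, ev_ok, 1)

    speed_ts = TimeSeries(times=head_velocity.times,
                          values=np.abs(head_velocity.values[0]),
                          rate=head_velocity.rate, units="deg/s")
    onsets = detect_onsets(speed_ts, threshold=onset_speed_thr,
                           min_pre_below=onset_pre, min_post_above=onset_post)
    aligned = None
    if len(onsets) == 0:
        warnings.warn("no rotational-movement onsets found")
    else:
        dt = float(np.median(np.diff(eye_velocity.times)))
        nwin = int(round(align_window / dt))
        rows = []
        for t0 in onsets.times:
            i = int(np.searchsorted(eye_velocity.times, t0))
            if i - nwin < 0 or i + nwin > ev.size:
                continue
            rows.append(ev[i - nwin:i + nwin])
        if rows:
            rows = np.asarray(rows)
            aligned = {
                "lags": (np.arange(-nwin, nwin) + 0.5) * dt,
                "mean": np.nanmean(rows, axis=0),
                "sem": np.nanstd(rows, axis=0, ddof=1) / np.sqrt(rows.shape[0]),
                "n": rows.shape[0],
            }

    a = (ev_ok - ev_ok.mean()) / (ev_ok.std() or 1)
    b_ = (he - he.mean()) / (he.std() or 1)
    xc = np.correlate(a, b_, mode="full") / a.size
    dt = float(np.median(np.diff(eye_velocity.times)))
    lags = np.arange(-a.size + 1, a.size) * dt
    return {"bin_centers": np.array(centers), "bin_means": np.array(means),
            "bin_sems": np.array(sems), "slope": float(slope),
            "intercept": float(intercept), "onsets": onsets,
            "onset_aligned": aligned, "xcorr": xc, "xcorr_lags": lags}
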