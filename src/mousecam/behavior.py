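"""Frequency-domain behavioral-state segmentation and permutation tests.

Mouse behavioral states (active exploration, quiescence, grooming,
eating) leave distinct spectral signatures in head-mounted
accelerometer signals — grooming strokes and chewing are narrowband
periodic, exploration is broadband, quiescence is silent.  A short-time
Fourier transform (Hann window 2 s, shift 40 ms) converts the 3-channel
trace into log-magnitude spectral feature vectors; a one-hidden-layer
MLP (100 rectified-linear units, Adam) classifies each window by the
state at its midpoint; performance is evaluated by 4-fold
cross-validation with contiguous temporal blocks (adjacent windows
overlap by 98%, so random splits would leak; the block split is this
package's choice and is stricter than a random one).

Condition comparisons (e.g. state occupancy with vs without the head
camera) use session-level permutation tests: the statistic is the L1
distance between condition-mean occupancy vectors (or a circular-mean /
circular-variance difference for orientation data), the null is built
by reassigning whole sessions to conditions, and p = (b + 1)/(n + 1)
where b counts permuted statistics >= the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import circmean, circvar
from sklearn.neural_network import MLPClassifier

from .containers import STATE_ORDER, StateLabels, TimeSeries

__all__ = [
    "SpectralFeatures",
    "stft_features",
    "label_windows",
    "train_state_classifier",
    "crossval_confusion",
    "permutation_test",
    "occupancy_permutation_test",
    "l1_mean_distance",
    "circular_mean_diff",
    "circular_variance_diff",
]

LOG_FLOOR = 1e-12


@dataclass
class SpectralFeatures:
    """STFT feature matrix: one row per window, 3 × n_freq_bins columns."""

    center_times: np.ndarray
    features: np.ndarray
    freq_axis: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]


def stft_features(
    accel: TimeSeries,
    window: float = 2.0,
    shift: float = 0.04,
    log_floor: float = LOG_FLOOR,
) -> SpectralFeatures:
    """Short-time Fourier features of a 3-channel accelerometer trace.

    Hann-windowed magnitude spectra per channel, log10-scaled with a
    floor of ``log_floor``, concatenated across channels.  Window count
    is floor((N − W)/S) + 1 (no padding); each window's reference time
    is its midpoint.
    """
    if accel.rate is None:
        dt = np.median(np.diff(accel.times))
        rate = 1.0 / float(dt)
    else:
        rate = float(accel.rate)
    nwin = int(round(window * rate))
    nshift = int(round(shift * rate))
    if abs(nwin - window * rate) > 1e-6 or nshift < 1:
        raise ValueError("window/shift not representable at the sampling rate")
    n = accel.n_samples
    if n < nwin:
        raise ValueError("trace shorter than one window")
    n_windows = (n - nwin) // nshift + 1
    taper = np.hanning(nwin)
    starts = np.arange(n_windows) * nshift
    freq_axis = np.fft.rfftfreq(nwin, 1.0 / rate)
    feats = np.empty((n_windows, accel.n_channels * freq_axis.size))
    for k, s in enumerate(starts):
        seg = accel.values[:, s:s + nwin] * taper
        mag = np.abs(np.fft.rfft(seg, axis=1))
        feats[k] = np.log10(np.maximum(mag, log_floor)).ravel()
    center_times = accel.times[0] + (starts + (nwin - 1) / 2.0) / rate
    return SpectralFeatures(center_times=center_times, features=feats,
                            freq_axis=freq_axis)


def label_windows(features: SpectralFeatures, labels: StateLabels) -> Tuple[np.ndarray, np.ndarray]:
    """Label each window by the state at its midpoint; drop unlabeled windows.

    Returns (window_indices, state_labels) for the labeled windows.
    """
    states = labels.states_at(features.center_times)
    keep = np.array([s is not None for s in states])
    return np.flatnonzero(keep), np.array([str(s) for s in states[keep]])


def train_state_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    hidden_units: int = 100,
    max_iter: int = 300,
    min_per_class: int = 4,
) -> MLPClassifier:
    """Fit the one-hidden-layer MLP state classifier (deterministic per seed)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < min_per_class:
            raise ValueError(f"class {cls!r} has only {cnt} windows (< {min_per_class})")
    clf = MLPClassifier(hidden_layer_sizes=(hidden_units,), activation="relu",
                        solver="adam", random_state=seed, max_iter=max_iter)
    clf.fit(np.asarray(features), labels)
    return clf


def crossval_confusion(
    features: np.ndarray,
    labels: Sequence[str],
    k: int = 4,
    seed: int = 0,
    order: Sequence[str] = STATE_ORDER,
    **clf_kw,
) -> Tuple[np.ndarray, float, np.ndarray]:
    """k-fold cross-validated confusion matrix with contiguous-block folds.

    Folds are contiguous blocks of windows in temporal order.  Returns
    (row-normalized confusion matrix in ``order``, overall accuracy,
    per-row sample counts).  Rows for absent classes are zero.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    n = labels.size
    bounds = np.linspace(0, n, k + 1).astype(int)
    present = set(np.unique(labels))
    preds = np.empty(n, dtype=labels.dtype)
    for f in range(k):
        test = np.zeros(n, dtype=bool)
        test[bounds[f]:bounds[f + 1]] = True
        train_labels = labels[~test]
        missing = present - set(np.unique(train_labels))
        if missing:
            raise ValueError(f"class {sorted(missing)} absent from training fold {f}")
        clf = train_state_classifier(features[~test], train_labels, seed=seed, **clf_kw)
        preds[test] = clf.predict(features[test])
    idx = {s: i for i, s in enumerate(order)}
    m = len(order)
    counts = np.zeros((m, m))
    for true, pred in zip(labels, preds):
        if true in idx and pred in idx:
            counts[idx[true], idx[pred]] += 1
    row_n = counts.sum(axis=1)
    conf = np.divide(counts, row_n[:, None], out=np.zeros_like(counts),
                     where=row_n[:, None] > 0)
    accuracy = float((preds == labels).mean())
    return conf, accuracy, row_n


# ---------------------------------------------------------------------------
# Permutation tests


def l1_mean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L1 distance between the column means of two (sessions × bins) arrays."""
    return float(np.abs(np.mean(a, axis=0) - np.mean(b, axis=0)).sum())


def circular_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute circular-mean difference (degrees) between two angle samples."""
    ma = circmean(np.deg2rad(np.ravel(a)))
    mb = circmean(np.deg2rad(np.ravel(b)))
    d = np.rad2deg(np.angle(np.exp(1j * (ma - mb))))
    return float(abs(d))


def circular_variance_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute circular-variance difference between two angle samples."""
    return float(abs(circvar(np.deg2rad(np.ravel(a))) - circvar(np.deg2rad(np.ravel(b)))))


def permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float] = l1_mean_distance,
    n_perm: int = 10000,
    seed: int = 0,
    exact_limit: int = 20000,
) -> dict:
    """Session-level permutation test of ``statistic(cond_a, cond_b)``.

    Whole sessions (rows) are reassigned between conditions.  When the
    number of distinct arrangements is below ``exact_limit`` the test
    enumerates all of them exactly (noted in the output); otherwise it
    draws ``n_perm`` random reassignments.  p = (b + 1)/(n + 1) with b
    the number of permuted statistics >= observed, so p is never 0.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 sessions per condition")
    observed = statistic(a, b)
    pooled = np.vstack([a, b])
    # canonical row order: the null does not depend on which condition was
    # passed first or on how sessions were ordered within a condition
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n_a, n_tot = a.shape[0], a.shape[0] + b.shape[0]
    n_arrangements = comb(n_tot, n_a)
    rng = np.random.default_rng(seed)
    null = []
    exact = n_arrangements < exact_limit
    if exact:
        for pick in combinations(range(n_tot), n_a):
            sel = np.zeros(n_tot, dtype=bool)
            sel[list(pick)] = True
            null.append(statistic(pooled[sel], pooled[~sel]))
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n_tot)
            null.append(statistic(pooled[perm[:n_a]], pooled[perm[n_a:]]))
    null = np.asarray(null)
    b_count = int(np.sum(null >= observed))
    if exact:
        # the identity arrangement is part of the enumeration, so b >= 1
        # and the plain fraction is already a valid exact p-value
        p = b_count / null.size
    else:
        p = (b_count + 1) / (null.size + 1)
    return {"statistic": observed, "p": p, "null": null, "exact": exact}


def occupancy_permutation_test(
    occupancy_a: np.ndarray,
    occupancy_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """L1 permutation test on per-session state-occupancy 4-vectors."""
    a = np.atleast_2d(np.asarray(occupancy_a, dtype=float))
    b = np.atleast_2d(np.asarray(occupancy_b, dtype=float))
    for name, m in (("occupancy_a", a), ("occupancy_b", b)):
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{name} rows must sum to 1")
    return permutation_test(a, b, statistic=l1_mean_distance,
                            n_perm=n_perm, seed=seed)
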