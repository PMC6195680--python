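# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Time base and containers

All internal times are seconds on the neural-acquisition clock; camera and
tracker clocks are converted at the I/O boundary. Camera frames are aligned
by subtracting the saved per-frame offset between the GPU acquisition
timestamp and the TTL pulse received by the recording system
(`io.align_frame_timestamps`); inter-frame intervals above 1.5× the median
are flagged as candidate dropped frames. The 1.5× criterion is a robustness
choice (the acquisition mechanism itself does not define one): at 30–90 Hz
frame rates it tolerates ordinary jitter while catching a missing frame.

## Head orientation and head movements

The head-mounted accelerometer measures gravity plus inertial acceleration
in the head frame (x naso-occipital, y interaural, z ventral–dorsal). The
gravity component is isolated by a zero-phase (forward–backward)
second-order Butterworth low-pass at 2 Hz; DC gain is exactly 1. The first
and last second of filtered traces are flagged edge-contaminated
(reflect-padded zero-phase filtering is least trustworthy there) and
excluded from summary statistics.

**Angle conventions.** Pitch is the signed angle between the gravity vector
and the y/z plane, `pitch = asin(−gx/|g|)`, positive nose-up. Roll is
implemented as the bank angle about the naso-occipital axis,
`roll = atan2(−gy, −gz)`, positive right-ear-down. The plane-angle
definition of roll (`asin(−gy/|g|)`) coincides with the bank angle at zero
pitch but cannot be combined with the pitch definition into an invertible
(pitch, roll) → gravity map over the full ±90°×±90° grid
(`sin²p + sin²r` can exceed 1); the bank-angle convention makes
render-then-recover an exact identity, which the orientation-recovery tests
rely on. Samples whose gravity-vector norm falls below 0.5 g are flagged
invalid rather than raising.

Head-movement magnitude is the per-sample Euclidean norm of the
gravity-subtracted 3-vector, then smoothed with the same zero-phase 2 Hz
low-pass. The norm is taken before smoothing; smoothing components first
would underestimate oscillatory movement whose direction rotates.

**Onset detection.** An onset is the first sample strictly above threshold
after the signal stayed at or below threshold for at least `min_pre_below`
seconds, provided it then stays strictly above for at least
`min_post_above` seconds. Defaults: threshold 0.0625 g, 0.5 s / 0.5 s for
head movements; whisking uses 0.1 s post; rotational movements use a
15 °/s speed threshold. Onsets whose window touches a masked sample
(e.g. body speed ≥ 1 cm/s) or the recording edge are dropped. Onset time is
reported at the first supra-threshold sample so rasters align
reproducibly.

**Yaw position** is the causal convolution of gyroscope yaw velocity with
`exp(−t/τ)`, τ = 1 s, truncated at 7τ. The leading kernel sample carries
half weight (trapezoidal rule), which makes the discrete sum agree with the
continuous convolution integral to O((dt/τ)²); discrete outputs correspond
to the continuous response evaluated half a sample late. A velocity step ω
settles at ωτ.

**Orientation histograms** bin the gravity direction on a 5° elevation ×
azimuth grid; counts are divided by the total count and by each bin's
quadrangle solid angle, so the density integrates to 1 over the sphere;
log10 density is reported with empty bins flagged.

## Body speed

Speed is the magnitude of the centered finite-difference velocity of the
tracked (x, y) position, boxcar-smoothed over 0.25 s. The window sits below
the 0.5 s onset-quiescence criterion so smoothing cannot smear a
locomotion bout across an onset window boundary.

## Pupil detection

Per frame: (1) contiguous pixels above the reflection threshold are masked
and filled by biharmonic inpainting (any smooth diffusion-style fill
suffices; the requirement is that a masked disk on a uniform background
comes back within ±2 intensity); a mask covering more than half the frame
raises (occlusion). (2) The frame is lightly Gaussian-smoothed (σ = 1 px),
thresholded, and the largest dark connected component's subpixel contour
(marching squares at the threshold level) is fit with a least-squares
ellipse. Largest-component selection is a deliberate choice: the pupil is
the dominant dark region of an eye frame. (3) Fits with region mean
intensity above, or ellipse area below, the configured criteria come back
invalid with a reason code (`no_contour`, `area_below_min`,
`intensity_above_max`) — never an exception, and raising the area floor can
only invalidate, never validate.

Thresholds are per-session configuration; in practice they were selected by
hand against a small sample of frames. `suggest_thresholds` offers an
Otsu-based starting point as a convenience only.

Image coordinates: origin top-left, x rightward, y downward, 0-based pixel
centers. Pixel-to-degree conversion is a configurable linear scale
(default 3 px/°); traces keep only frames with a valid fit — gaps are never
interpolated. A 3-tap smoothing kernel (0.072, 0.855, 0.072) is provided
for display; analyses use raw fits, and the smoother never bridges gaps.

**Dark-condition eye tracking.** When the dilated pupil defeats ellipse
fitting, eye position is approximated by integrating dense optical flow of
the pupil edges: frames are median-filtered (15 px window) so hair and LED
glints do not contaminate the flow, Gaussian-smoothed (σ = 2 px) so the
local least-squares (iterative Lucas–Kanade) flow stays stable on step
edges, and the flow averaged over strong-gradient pixels is summed over
frames. The integration is leak-prone over long spans; it is intended for
initial eye movements after an onset.

## Camera stability and whisking

Registration compares each frame's ROI against the pixelwise-mean reference
ROI over integer shifts within a search radius, maximizing Pearson
correlation; ties break toward the smaller shift. Sub-pixel interpolation is
deliberately not used — displacements are reported in whole pixels, the
resolution of the stability claim. Frames whose mean ROI brightness
deviates more than 3 SD are excluded (reason `brightness`); the reference
is built in two passes (provisional mean → exclusions → final mean) so the
exclusion rule and the averaging interact deterministically. Inter-frame
image movement is the norm of the change in displacement between
consecutive non-excluded frames, in µm; covariate-binned summaries use
configurable bins (2 cm/s body speed, 0.1 g head acceleration by default).

Whisker-pad movement is the spatial mean of dense optical flow over a
rectangular ROI, one (horizontal, vertical) pair per frame transition;
analyses use the horizontal component. Whisking frequency is the spectral
peak of the horizontal flow per sliding window, kept only when it exceeds
5× the median in-band power (silent windows contribute nothing), and
histogrammed per behavioral state.

## Behavioral-state segmentation

Features: STFT of the three accelerometer channels (Hann window 2 s, shift
40 ms, no padding; window count `floor((N−W)/S)+1`), log10 magnitudes with
a 1e-12 floor, concatenated across channels. Each window takes the label of
the state interval containing its midpoint; unlabeled windows are dropped;
intervals shorter than 2 s are rejected at construction. The classifier is
an MLP with one hidden layer of 100 rectified-linear units trained with
Adam (the learning rate, epochs and regularization are configuration with
library defaults; they are not critical on separable spectra).

Cross-validation uses contiguous temporal blocks, not random windows:
adjacent 2 s windows overlap by 98%, so random splits would leak training
data into the test folds and inflate accuracy. This is stricter than a
random split and is flagged here deliberately.

Permutation tests operate at the session level: the statistic (L1 distance
between condition-mean occupancy vectors, or circular-mean / circular-
variance differences for orientations, or L1 between speed distributions)
is recomputed under random reassignment of whole sessions to conditions,
10 000 draws by default, with p = (b+1)/(n+1). When fewer than 2×10⁴
distinct arrangements exist the test enumerates all of them exactly (noted
in the output; the plain fraction is then the exact p). Pooled rows are
canonically sorted before permuting, so p does not depend on argument order
or session ordering.

## Eye–head models

For each eye sample, head pitch and roll (and optionally leaky-integrated
yaw position) are linearly interpolated at lags −500…0 ms in 25 ms steps
(21 lags per signal); rows whose history leaves the recorded span are
dropped. The linear model is fit by automatic relevance determination —
evidence maximization with one precision per coefficient — which shrinks
irrelevant lags smoothly; hard pruning is disabled so a noiseless,
identifiable design is recovered to numerical precision. The nonlinear
alternative is an MLP regressor (100 rectified-linear units, seeded).
Performance is pooled R² = 1 − rss/tss on concatenated held-out predictions
from contiguous-block 5-fold cross-validation (blocked for the same leakage
reason as above). Interocular error correlation is the Pearson correlation
of the two eyes' residuals on simultaneous valid samples.

Saccade-like eye movements are local maxima of eye speed (central
differences within contiguous valid runs; never across gaps) above
250 °/s; displacement spans ±20 ms around the peak; context is head-still
when the movement magnitude at the peak is below 0.0625 g. Saccade–head
timing uses the gap to the preceding movement offset (and subsequent
onset — interval edges, since "preceding/subsequent" is otherwise
ambiguous); the null places the same number of events uniformly within the
head-still intervals; the statistic is the two-sample KS distance to the
pooled null, with a Monte-Carlo p from per-simulation KS values.

## Neural analyses

Welch PSD: 2 s Hann window, 1 s overlap, density normalization (integral ≈
variance). PSD ratios are elementwise with zero-denominator bins flagged
NaN; within-condition variability is the SD of ratios over non-overlapping
60 s segments. Spike SNR is mean power in ±1 ms spike windows over mean
power of samples at least 2 ms from every spike. LFP band power: zero-phase
4th-order Butterworth bandpass (2–10 or 10–20 Hz), squared, smoothed with a
2 s-SD Gaussian, optionally normalized so mean quiescent low-band power
is 1. Pupil–LFP correlation is computed within head-still segments
(magnitude < 0.02 g sustained ≥ 15 s; the stillness threshold is
configuration — only the duration is pinned), with a circular-shift null
(shifts ≥ 5 s, 1000 draws).

The modulation index uses exact spike counts in the 1 s windows before and
after each onset (not binned counts; rasters default to 50 ms bins for
display only): `MI = (Npost − Npre)/(Npost + Npre)`, no baseline
subtraction, undefined (flagged) when both windows are empty. Significance
is a Wilcoxon signed-rank on the per-event count pairs, zero-difference
pairs dropped, exact distribution at small n. The significance level for
calling a cell "modulated" is left to the caller; no multiple-comparison
policy is imposed.

Onset splitting by eye predictability: the initial eye movement is the
displacement vector at the earliest strict local extremum of either
displacement component within 100 ms after the onset (the extremum of a 2-D
trace is otherwise ill-defined; this choice is documented rather than
implied); onsets lacking an in-window extremum, in either the measured or
predicted trace, or with a zero-length vector, are excluded and counted.
Cosine similarity ≥ 0.5 defines the "predictable" group.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic per seed and return the ground truth their
consumer's recovery test needs.

- **Accelerometer sessions**: gravity from a smooth reflected random walk on
  (pitch, roll) (Gaussian increments, 2 °/√s when active, slower when
  quiescent, reflected at ±60°), plus a state-specific oscillation
  (grooming ~6 Hz, eating ~4 Hz, active broadband 2–20 Hz, quiescence
  silent; amplitudes ~0.1 g) and white noise (0.004 g SD). These bands
  reproduce the spectral separability the segmentation exploits; they are
  configuration, not measured constants, and real grooming kinematics are
  richer. State segments are ≥ 2 s by construction.
- **Eye video**: a dark filled ellipse on a bright background, anti-aliased
  by 4× area averaging, optional saturated reflection disk straddling the
  pupil boundary, additive Gaussian noise. No iris texture, eyelids or
  blinks — pass rates here bound geometry errors only, not occlusion
  handling.
- **Eye–head datasets**: the forward lagged linear model applied to smooth
  Gaussian-process head signals with power up to 15 Hz. The bandwidth
  matters: per-lag weights are identifiable only when the head signal
  decorrelates across the 25 ms lag grid. Real pitch/roll extracted through
  a 2 Hz gravity filter is smoother, so on real data the individual lag
  weights are identified only up to the signal's bandwidth even when
  predictions are accurate — a known limitation of the lag-resolved
  interpretation.
- **Spike trains**: inhomogeneous Poisson with the rate stepped to
  `baseline × (1+MI)/(1−MI)` for exactly 1 s after each onset, making the
  expected modulation index analytic (MI = 0.5 ⇔ rate ratio 3). Real
  movement-locked responses have latency and adaptation structure this
  step model does not attempt.

## Problem sizes used by the acceptance script

Orientation recovery: 1000 random angle pairs, 60 s of 100 Hz trace with
0.3 g, 20 Hz movement noise. Pupil fitting: 100 rendered ellipses (noise
SD 5), 20 reflection cases. Registration: 20 stacks × 12 frames, shifts
|d| ≤ 5 px. Onset oracle: 50 piecewise traces of 30 s at 50 Hz. Eye–head:
~20 000 eye samples at 50 Hz, signal:noise 4:1 (population R² 0.8).
Segmentation: 400 s four-state session, 2 s windows at 0.2 s shift (the
STFT default shift is 40 ms; the coarser shift keeps the window count at a
size a desk machine fits in seconds without changing separability).
Permutation calibration: 500 replicate tests of 10 + 10 sessions at 500
permutations each. Wilcoxon power: 1000 replicates of 50 events at rate
ratio 2. These sizes are the package's own choices for a reproducible desk-
scale report; all are parameters of the underlying functions.
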