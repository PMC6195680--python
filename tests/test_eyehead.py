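"""Lagged eye-head regression (ARD and MLP), cross-validated R²,
interocular residual correlation, saccade detection and timing."""

import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from mousecam.containers import TimeSeries
from mousecam import eyehead
from mousecam.eyehead import LaggedDesign
from mousecam.synthetic import LAG_GRID_S, N_LAGS, gen_eyehead_dataset

warnings.filterwarnings("ignore", category=ConvergenceWarning)

K_PITCH = 0.5 * np.exp(-((LAG_GRID_S + 0.1) / 0.08) ** 2)
K_ROLL = -0.4 * np.exp(-((LAG_GRID_S + 0.05) / 0.1) ** 2)
K_TRUE = np.concatenate([K_PITCH, K_ROLL])


def head_eye_ts(pitch, roll, eye, rate=50.0):
    n = len(pitch)
    t = np.arange(n) / rate
    head = TimeSeries(times=t, values=np.vstack([pitch, roll]), rate=rate,
                      channel_names=["pitch", "roll"])
    eye_ts = TimeSeries(times=t, values=np.asarray(eye, float), rate=rate)
    return head, eye_ts


class TestBuildLaggedDesign:
    def test_constant_signals_constant_rows(self):
        n = 200
        head, eye = head_eye_ts(np.full(n, 10.0), np.full(n, -5.0), np.zeros(n))
        d = eyehead.build_lagged_design(head, eye)
        np.testing.assert_allclose(d.block("pitch"), 10.0, atol=1e-12)
        np.testing.assert_allclose(d.block("roll"), -5.0, atol=1e-12)

    def test_ramp_rows_match_interpolation_oracle(self):
        rate, a = 50.0, 3.0
        n = 300
        t = np.arange(n) / rate
        head, eye = head_eye_ts(a * t, np.zeros(n), np.zeros(n))
        d = eyehead.build_lagged_design(head, eye)
        # row i of the pitch block is a*(t_i + lags)
        expected = a * (d.times[:, None] + LAG_GRID_S[None, :])
        np.testing.assert_allclose(d.block("pitch"), expected, atol=1e-9)

    def test_column_count_21_per_signal(self):
        n = 200
        head, eye = head_eye_ts(np.zeros(n), np.zeros(n), np.zeros(n))
        d = eyehead.build_lagged_design(head, eye)
        assert d.X.shape[1] == 2 * N_LAGS == 42

    def test_rows_without_full_history_dropped(self):
        n = 200
        head, eye = head_eye_ts(np.zeros(n), np.zeros(n), np.zeros(n))
        d = eyehead.build_lagged_design(head, eye)
        assert d.times.min() >= head.times[0] + 0.5 - 1e-9

    def test_empty_overlap_rejected(self):
        head, _ = head_eye_ts(np.zeros(100), np.zeros(100), np.zeros(100))
        eye = TimeSeries(times=np.arange(100) / 50.0 + 100.0, values=np.zeros(100))
        with pytest.raises(ValueError, match="overlap"):
            eyehead.build_lagged_design(head, eye)


class TestFitLinearARD:
    def test_noiseless_identifiability(self):
        head, eye, truth = gen_eyehead_dataset(K_PITCH, K_ROLL, k0=5.0,
                                               noise_sd=0.0, duration=60, seed=2)
        d = eyehead.build_lagged_design(head, eye)
        model, report = eyehead.fit_linear_ard(d)
        assert report.r2 == pytest.approx(1.0, abs=1e-6)
        assert np.abs(model.weights - K_TRUE).max() < 1e-6
        assert model.k0 == pytest.approx(5.0, abs=1e-6)

    def test_pure_noise_block_shrunk(self, rng):
        head, eye, truth = gen_eyehead_dataset(
            K_PITCH, K_ROLL, noise_sd=5.0, duration=120, seed=3)
        d = eyehead.build_lagged_design(head, eye)
        X = np.hstack([d.X, rng.standard_normal((d.n_rows, N_LAGS)) * 15.0])
        d3 = LaggedDesign(X=X, y=d.y, times=d.times,
                          signals=("pitch", "roll", "yaw"))
        model, _ = eyehead.fit_linear_ard(d3)
        informative = np.abs(np.concatenate([model.k_pitch, model.k_roll])).mean()
        noise_block = np.abs(model.k_yaw).mean()
        assert noise_block < 0.1 * informative

    def test_sigma2_estimates_noise_variance(self):
        head, eye, truth = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=4.0,
                                               duration=200, seed=4)
        d = eyehead.build_lagged_design(head, eye)
        model, _ = eyehead.fit_linear_ard(d)
        assert model.sigma2 == pytest.approx(16.0, rel=0.1)


class TestCrossvalR2:
    def test_perfect_predictor_r2_one(self):
        head, eye, _ = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=0.0,
                                           duration=60, seed=5)
        d = eyehead.build_lagged_design(head, eye)
        rep = eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)
        assert rep.r2 == pytest.approx(1.0, abs=1e-6)

    def test_r2_identity_recomputed(self):
        head, eye, _ = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=3.0,
                                           duration=90, seed=6)
        d = eyehead.build_lagged_design(head, eye)
        rep = eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)
        assert rep.r2 == pytest.approx(1 - rep.rss / rep.tss, abs=1e-12)

    def test_noise_target_mean_only_model_near_zero(self, rng):
        n = 2000
        y = rng.standard_normal(n)
        X = rng.standard_normal((n, N_LAGS * 2))

        class MeanModel:
            def __init__(self, mu):
                self.mu = mu

            def predict(self, X):
                return np.full(X.shape[0], self.mu)

        def mean_fitter(design):
            model = eyehead.EyeHeadModel(kind="linear-ard",
                                         regressor=MeanModel(design.y.mean()))
            return model, None

        d = LaggedDesign(X=X, y=y, times=np.arange(n) / 50.0)
        rep = eyehead.crossval_r2(mean_fitter, d, k=5)
        # pooled R2 of the null model is <= 0 in expectation, close to 0
        assert rep.r2 < 0.02
        assert rep.r2 > -3 / np.sqrt(n) - 0.05

    def test_cv_r2_below_noise_ceiling(self):
        head, eye, truth = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=10.0,
                                               duration=200, seed=7)
        d = eyehead.build_lagged_design(head, eye)
        rep = eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)
        ceiling = 1 - 100.0 / eye.values[0].var()
        assert rep.r2 <= ceiling + 0.02

    def test_tiny_fold_rejected(self):
        d = LaggedDesign(X=np.zeros((6, 42)), y=np.zeros(6), times=np.arange(6.0))
        with pytest.raises(ValueError, match="fold"):
            eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)


class TestFitNonlinear:
    def test_constructed_nonlinearity_beats_linear(self):
        # eye = |pitch at lag 0|: an even nonlinearity with zero linear
        # component, so the linear model can explain almost nothing while
        # the MLP captures it
        head, eye, _ = gen_eyehead_dataset(np.zeros(N_LAGS), np.zeros(N_LAGS),
                                           noise_sd=0.0, duration=120, seed=8)
        d = eyehead.build_lagged_design(head, eye)
        y = np.abs(d.block("pitch")[:, -1])
        d = LaggedDesign(X=d.X, y=y, times=d.times)
        lin = eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)
        mlp = eyehead.crossval_r2(lambda dd: eyehead.fit_nonlinear(dd, seed=0), d, k=5)
        assert mlp.r2 > 0.8
        assert lin.r2 < 0.3

    def test_capacity_on_linear_truth(self):
        head, eye, _ = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=2.0,
                                           duration=120, seed=9)
        d = eyehead.build_lagged_design(head, eye)
        lin = eyehead.crossval_r2(eyehead.fit_linear_ard, d, k=5)
        mlp = eyehead.crossval_r2(lambda dd: eyehead.fit_nonlinear(dd, seed=0), d, k=5)
        assert mlp.r2 >= lin.r2 - 0.05

    def test_deterministic_given_seed(self):
        head, eye, _ = gen_eyehead_dataset(K_PITCH, K_ROLL, noise_sd=2.0,
                                           duration=60, seed=10)
        d = eyehead.build_lagged_design(head, eye)
        m1, _ = eyehead.fit_nonlinear(d, seed=4)
        m2, _ = eyehead.fit_nonlinear(d, seed=4)
        np.testing.assert_array_equal(m1.predict(d.X), m2.predict(d.X))


class TestInterocularCorrelation:
    def test_shared_residual_perfect_correlation(self, rng):
        shared = rng.standard_normal(500)
        pred = rng.standard_normal(500)
        cc = eyehead.interocular_error_correlation(pred + shared, pred,
                                                   -pred + shared, -pred)
        assert cc == pytest.approx(1.0, abs=1e-9)

    def test_independent_residuals_near_zero(self, rng):
        n = 5000
        cc = eyehead.interocular_error_correlation(
            rng.standard_normal(n), np.zeros(n),
            rng.standard_normal(n), np.zeros(n))
        assert abs(cc) < 3 / np.sqrt(n)

    def test_mixture_correlation_closed_form(self, rng):
        n, rho = 10_000, 0.5
        shared = rng.standard_normal(n)
        left = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
        right = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
        cc = eyehead.interocular_error_correlation(left, np.zeros(n),
                                                   right, np.zeros(n))
        assert cc == pytest.approx(rho, abs=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="joint samples"):
            eyehead.interocular_error_correlation(np.zeros(5), np.zeros(5),
                                                  np.zeros(5), np.zeros(5))


def brute_force_saccades(times, h, v, speed_thr):
    """Independent peak-scan oracle (no gaps in the trace)."""
    vh = np.gradient(h, times)
    vv = np.gradient(v, times)
    s = np.hypot(vh, vv)
    peaks = []
    for i in range(1, len(s) - 1):
        if s[i] > speed_thr and s[i] >= s[i - 1] and s[i] > s[i + 1]:
            peaks.append(times[i])
    return np.array(peaks)


def eye_ts_from_hv(h, v, rate=200.0):
    t = np.arange(len(h)) / rate
    return TimeSeries(times=t, values=np.vstack([h, v]), rate=rate, units="deg")


class TestDetectSaccades:
    def test_transient_during_head_still(self):
        rate = 200.0
        n = 400
        h = np.zeros(n)
        h[200:] = 5.0  # 5 deg jump in one sample: speed = 1000 deg/s
        eye = eye_ts_from_hv(h, np.zeros(n), rate)
        head_mag = TimeSeries(times=eye.times, values=np.full(n, 0.01), rate=rate)
        events = eyehead.detect_saccades(eye, head_mag)
        assert len(events) == 1
        assert events[0].context == "head-still"
        assert events[0].dh == pytest.approx(5.0, abs=0.5)

    def test_same_transient_during_head_movement(self):
        rate = 200.0
        n = 400
        h = np.zeros(n)
        h[200:] = 5.0
        eye = eye_ts_from_hv(h, np.zeros(n), rate)
        head_mag = TimeSeries(times=eye.times, values=np.full(n, 0.1), rate=rate)
        events = eyehead.detect_saccades(eye, head_mag)
        assert len(events) == 1
        assert events[0].context == "head-moving"

    def test_slow_ramp_no_detection(self):
        rate = 200.0
        t = np.arange(400) / rate
        eye = eye_ts_from_hv(100.0 * t, np.zeros(400), rate)
        assert eyehead.detect_saccades(eye) == []

    @pytest.mark.parametrize("case", range(100))
    def test_equals_brute_force_oracle(self, case):
        rng = np.random.default_rng(3000 + case)
        rate = 100.0
        n = 500
        h = np.cumsum(rng.normal(0, 1.0, n))
        v = np.cumsum(rng.normal(0, 1.0, n))
        eye = eye_ts_from_hv(h, v, rate)
        got = np.array([e.peak_time for e in eyehead.detect_saccades(eye)])
        expect = brute_force_saccades(eye.times, h, v, 250.0)
        np.testing.assert_array_equal(got, expect)


class TestSaccadeHeadTiming:
    def _setup(self, rng, n_sacc=30):
        moves = np.array([[10.0 * k, 10.0 * k + 2.0] for k in range(1, 21)])
        still = np.array([[10.0 * k + 2.0, 10.0 * (k + 1)] for k in range(1, 20)])
        return moves, still

    def test_uniform_saccades_not_significant_in_most_runs(self):
        rng = np.random.default_rng(0)
        moves, still = self._setup(rng)
        durs = still[:, 1] - still[:, 0]
        n_nonsig = 0
        n_runs = 40
        for r in range(n_runs):
            seg = rng.choice(len(durs), size=30, p=durs / durs.sum())
            sacc = np.sort(still[seg, 0] + rng.uniform(0, 1, 30) * durs[seg])
            res = eyehead.saccade_head_timing(sacc, moves, still, n_sim=60, seed=r)
            n_nonsig += res["p"] > 0.05
        assert n_nonsig >= 0.85 * n_runs

    def test_clustered_saccades_detected(self):
        rng = np.random.default_rng(1)
        moves, still = self._setup(rng)
        # all saccades 50 ms after a movement offset
        sacc = moves[:19, 1] + 0.05 + rng.uniform(0, 0.001, 19)
        sacc = np.concatenate([sacc, moves[:15, 1] + 0.051])
        res = eyehead.saccade_head_timing(np.sort(sacc), moves, still,
                                          n_sim=200, seed=0)
        assert res["p"] < 0.01

    def test_empty_saccade_list_rejected(self):
        with pytest.raises(ValueError, match="empty|at least"):
            eyehead.saccade_head_timing(np.array([]), np.array([[0.0, 1.0]]),
                                        np.array([[1.0, 2.0]]))


class TestVelocityCoupling:
    def _head_velocity(self, rng, n=6000, rate=100.0):
        from scipy.signal import butter, filtfilt

        b, a = butter(2, 5.0, fs=rate)
        x = filtfilt(b, a, rng.standard_normal(n)) * 100
        return TimeSeries(times=np.arange(n) / rate, values=x, rate=rate)

    def test_compensatory_slope_recovered(self, rng):
        head = self._head_velocity(rng)
        eye_v = -0.6 * head.values[0] + rng.normal(0, 5, head.n_samples)
        eye = TimeSeries(times=head.times, values=eye_v, rate=head.rate)
        res = eyehead.eye_head_velocity_coupling(eye, head)
        assert res["slope"] == pytest.approx(-0.6, abs=0.05)

    def test_independent_traces_zero_slope(self, rng):
        head = self._head_velocity(rng)
        eye = TimeSeries(times=head.times,
                         values=rng.normal(0, 5, head.n_samples), rate=head.rate)
        res = eyehead.eye_head_velocity_coupling(eye, head)
        se = 5 / (head.values[0].std() * np.sqrt(head.n_samples))
        assert abs(res["slope"]) < 5 * se + 0.01

    def test_autocorrelation_peaks_at_zero_lag(self, rng):
        head = self._head_velocity(rng)
        eye = TimeSeries(times=head.times, values=head.values[0].copy(),
                         rate=head.rate)
        res = eyehead.eye_head_velocity_coupling(eye, head)
        assert res["xcorr_lags"][np.argmax(res["xcorr"])] == pytest.approx(0.0)
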