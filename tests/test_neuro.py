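"""PSD estimation and ratios, spike SNR, LFP band power, pupil-LFP
correlation, event alignment, and the modulation index."""

import numpy as np
import pytest

from mousecam.containers import EventTable, SpikeTrain, TimeSeries
from mousecam import neuro


def lfp_ts(x, rate=200.0):
    return TimeSeries(times=np.arange(len(x)) / rate, values=np.asarray(x, float),
                      rate=rate)


class TestWelchPsd:
    def test_sinusoid_peak_bin(self):
        t = np.arange(12000) / 200.0
        f, psd = neuro.welch_psd(np.sin(2 * np.pi * 10 * t), 200.0)
        assert f[np.argmax(psd)] == pytest.approx(10.0, abs=0.5)

    def test_doubling_amplitude_quadruples_power(self, rng):
        x = rng.standard_normal(12000)
        f, p1 = neuro.welch_psd(x, 200.0)
        _, p2 = neuro.welch_psd(2 * x, 200.0)
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_variance_integral(self, rng):
        x = rng.standard_normal(200 * 60)
        f, psd = neuro.welch_psd(x, 200.0)
        assert np.trapezoid(psd, f) == pytest.approx(1.0, rel=0.05)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            neuro.welch_psd(np.zeros(100), 200.0)


class TestPsdRatio:
    def test_identical_segments_unity(self, rng):
        x = rng.standard_normal(4000)
        _, p = neuro.welch_psd(x, 200.0)
        np.testing.assert_allclose(neuro.psd_ratio(p, p), 1.0)

    def test_scaled_signal_power_ratio_four(self, rng):
        x = rng.standard_normal(4000)
        _, p1 = neuro.welch_psd(x, 200.0)
        _, p2 = neuro.welch_psd(2 * x, 200.0)
        np.testing.assert_allclose(neuro.psd_ratio(p2, p1), 4.0, rtol=1e-9)

    def test_zero_denominator_flagged_nan(self):
        ratio = neuro.psd_ratio(np.array([1.0, 2.0]), np.array([1.0, 0.0]))
        assert ratio[0] == 1.0 and np.isnan(ratio[1])

    def test_segmentwise_sd_matches_enumeration(self, rng):
        fs = 200.0
        xa = rng.standard_normal(int(fs * 300))
        xb = rng.standard_normal(int(fs * 300))
        f, mean_r, sd_r = neuro.segment_psd_ratio_sd(xa, xb, fs, segment=60.0)
        # independent recomputation
        ratios = []
        nseg = int(60 * fs)
        for i in range(5):
            _, pa = neuro.welch_psd(xa[i * nseg:(i + 1) * nseg], fs)
            _, pb = neuro.welch_psd(xb[i * nseg:(i + 1) * nseg], fs)
            ratios.append(pa / pb)
        np.testing.assert_allclose(sd_r, np.std(ratios, axis=0, ddof=1), rtol=1e-9)


class TestSpikeSnr:
    def test_grows_with_amplitude_squared(self, rng):
        fs = 20000.0
        n = int(fs * 10)
        sigma = 1.0
        trace = rng.normal(0, sigma, n)
        spike_times = np.arange(0.5, 9.5, 0.1)
        for amp in (5.0, 10.0):
            tr = trace.copy()
            half = int(0.001 * fs)
            for st in spike_times:
                i = int(st * fs)
                tr[i - half:i + half + 1] += amp
            snr = neuro.spike_snr(tr, fs, spike_times)
            expected = 1 + amp ** 2 / sigma ** 2
            assert snr == pytest.approx(expected, rel=0.2)

    def test_pure_noise_snr_near_one(self, rng):
        fs = 20000.0
        trace = rng.standard_normal(int(fs * 5))
        fake = np.arange(0.5, 4.5, 0.05)
        snr = neuro.spike_snr(trace, fs, fake)
        n_spike_samples = fake.size * (2 * int(0.001 * fs) + 1)
        se = np.sqrt(2.0 / n_spike_samples)  # SE of a chi-square mean ratio
        assert abs(snr - 1.0) < 4 * se

    def test_margin_exclusion_sample_counts(self):
        fs = 1000.0
        trace = np.zeros(int(fs * 2))
        spike_times = np.array([0.5, 1.0])
        # count samples excluded from the noise estimate: +-2 ms per spike
        marg = int(0.002 * fs)
        excl = np.zeros(trace.size, bool)
        for st in spike_times:
            i = int(st * fs)
            excl[i - marg:i + marg + 1] = True
        trace[excl] = np.nan  # noise mean over NaNs would propagate
        trace[~excl] = 1.0
        snr = neuro.spike_snr(np.nan_to_num(trace, nan=0.0) + 1e-12, fs, spike_times)
        assert np.isfinite(snr)  # bookkeeping only: margin removed the NaN samples

    def test_no_noise_samples_rejected(self):
        # spikes every 4 ms with a +-2 ms margin blanket the whole trace
        with pytest.raises(ValueError, match="inter-spike"):
            neuro.spike_snr(np.zeros(100), 1000.0, np.arange(0.002, 0.0985, 0.004))


class TestLfpBandPower:
    def test_sinusoid_band_power_half(self):
        fs = 200.0
        t = np.arange(int(fs * 120)) / fs
        lfp = lfp_ts(np.sin(2 * np.pi * 5 * t), fs)
        low = neuro.lfp_band_power(lfp, band=(2, 10), smooth_sd=2.0)
        interior = low.values[0][int(10 * fs):-int(10 * fs)]
        assert interior.mean() == pytest.approx(0.5, rel=0.05)
        high = neuro.lfp_band_power(lfp, band=(10, 20), smooth_sd=2.0)
        assert high.values[0][int(10 * fs):-int(10 * fs)].mean() < 0.01 * 0.5

    def test_white_noise_bandwidth_ratio(self, rng):
        fs = 200.0
        lfp = lfp_ts(rng.standard_normal(int(fs * 300)), fs)
        low = neuro.lfp_band_power(lfp, band=(2, 10), smooth_sd=0)
        high = neuro.lfp_band_power(lfp, band=(10, 20), smooth_sd=0)
        ratio = low.values[0].mean() / high.values[0].mean()
        assert ratio == pytest.approx(8.0 / 10.0, rel=0.15)

    def test_normalization_unit_mean(self, rng):
        lfp = lfp_ts(rng.standard_normal(4000))
        mask = np.zeros(4000, bool)
        mask[1000:3000] = True
        bp = neuro.lfp_band_power(lfp, quiescent_mask=mask, normalize=True)
        assert bp.values[0][mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            neuro.lfp_band_power(lfp_ts(np.zeros(1000), rate=30.0), band=(10, 20))


class TestStillSegmentsAndPupilLfp:
    def test_short_still_segment_excluded(self):
        rate = 100.0
        mag = np.full(int(40 * rate), 0.1)
        mag[:int(14 * rate)] = 0.001  # 14 s still: too short
        segs = neuro.find_still_segments(lfp_ts(mag, rate), min_duration=15.0)
        assert segs.size == 0
        mag[:int(16 * rate)] = 0.001
        segs = neuro.find_still_segments(lfp_ts(mag, rate), min_duration=15.0)
        assert len(segs) == 1

    def test_anticorrelated_pupil_detected(self, rng):
        rate = 50.0
        n = int(rate * 60)
        from scipy.ndimage import gaussian_filter1d

        bp_vals = gaussian_filter1d(rng.standard_normal(n), 50) + 2.0
        bp = lfp_ts(bp_vals, rate)
        pupil = lfp_ts(-bp_vals + rng.normal(0, 0.01, n), rate)
        head = lfp_ts(np.full(n, 0.001), rate)
        res = neuro.pupil_lfp_correlation(bp, pupil, head, n_shuffle=50, seed=0)
        assert np.median(res["cc"]) < -0.9

    def test_independent_signals_within_null_spread(self, rng):
        rate = 50.0
        n = int(rate * 60)
        from scipy.ndimage import gaussian_filter1d

        bp = lfp_ts(gaussian_filter1d(rng.standard_normal(n), 50), rate)
        pupil = lfp_ts(gaussian_filter1d(rng.standard_normal(n), 50), rate)
        head = lfp_ts(np.full(n, 0.001), rate)
        res = neuro.pupil_lfp_correlation(bp, pupil, head, n_shuffle=200, seed=0)
        lo, hi = np.quantile(res["null"], [0.01, 0.99])
        assert lo <= np.median(res["cc"]) <= hi

    def test_no_still_segment_warns(self, rng):
        head = lfp_ts(np.full(1000, 0.5), 50.0)
        with pytest.warns(UserWarning, match="still"):
            res = neuro.pupil_lfp_correlation(head, head, head)
        assert res["cc"].size == 0


class TestAlignment:
    def test_raster_conserves_spike_count(self, rng):
        spikes = SpikeTrain(unit_id=0, spike_times=np.sort(rng.uniform(0, 100, 2000)))
        events = EventTable(times=np.arange(5.0, 95.0, 5.0))
        raster = neuro.align_spikes(spikes, events, window=(-1, 1), bin_width=0.05)
        # brute-force window count
        total = sum(np.sum((spikes.spike_times >= t - 1) & (spikes.spike_times < t + 1))
                    for t in raster.event_times)
        assert raster.counts.sum() == total

    def test_planted_spikes_peak_in_correct_bin(self):
        events = EventTable(times=np.arange(5.0, 95.0, 5.0))
        st = np.sort(np.concatenate([events.times + 0.052, [0.1, 99.0]]))
        raster = neuro.align_spikes(SpikeTrain(unit_id=0, spike_times=st), events)
        rate, _ = raster.psth()
        peak_bin = raster.bin_centers[np.argmax(rate)]
        assert 0.05 <= peak_bin <= 0.10

    def test_homogeneous_poisson_flat_psth(self):
        rng = np.random.default_rng(42)
        rate_hz, dur = 20.0, 400.0
        spikes = SpikeTrain(unit_id=0,
                            spike_times=np.sort(rng.uniform(0, dur, int(rate_hz * dur))))
        events = EventTable(times=np.arange(5.0, dur - 5.0, 4.0))
        raster = neuro.align_spikes(spikes, events, window=(-1, 1), bin_width=0.1)
        counts_per_bin = raster.counts.sum(axis=0)
        expected = rate_hz * 0.1 * raster.counts.shape[0]
        # Poisson 3-sigma bounds per bin
        assert np.all(np.abs(counts_per_bin - expected) < 3 * np.sqrt(expected) + 1)

    def test_edge_events_dropped_and_counted(self, rng):
        spikes = SpikeTrain(unit_id=0, spike_times=np.sort(rng.uniform(0, 10, 100)))
        events = EventTable(times=np.array([0.2, 5.0, 9.9]))
        raster = neuro.align_spikes(spikes, events, window=(-1, 1),
                                    recording_span=(0, 10))
        assert raster.n_dropped == 2

    def test_align_trace_mean_and_edges(self):
        trace = lfp_ts(np.arange(1000, dtype=float), 100.0)
        events = EventTable(times=np.array([0.001, 5.0, 9.999]))
        res = neuro.align_trace(trace, events, window=(-1, 1))
        assert res["n_dropped"] == 2
        assert res["aligned"].shape[0] == 1


class TestModulationIndex:
    def _train_with_counts(self, events, pre_counts, post_counts):
        times = []
        for t, npre, npost in zip(events.times, pre_counts, post_counts):
            times.extend(np.linspace(t - 0.9, t - 0.1, npre))
            times.extend(np.linspace(t + 0.1, t + 0.9, npost))
        return SpikeTrain(unit_id=0, spike_times=np.sort(np.array(times)))

    def test_mi_exact_cases(self):
        events = EventTable(times=np.arange(2.0, 42.0, 4.0))
        n = len(events)
        cases = [
            (10, 30, 0.5),   # (30-10)/(30+10)
            (10, 10, 0.0),
            (0, 5, 1.0),
        ]
        for npre, npost, expected in cases:
            train = self._train_with_counts(events, [npre] * n, [npost] * n)
            res = neuro.modulation_index(train, events,
                                         recording_span=(0.0, 44.0))
            assert res.mi == pytest.approx(expected, abs=1e-12)

    def test_no_spikes_undefined_flag(self):
        events = EventTable(times=np.array([5.0]))
        train = SpikeTrain(unit_id=0, spike_times=np.array([20.0]))
        res = neuro.modulation_index(train, events, recording_span=(0, 30))
        assert not res.defined

    def test_antisymmetric_under_window_swap(self, rng):
        spikes = SpikeTrain(unit_id=0, spike_times=np.sort(rng.uniform(0, 100, 800)))
        events = EventTable(times=np.arange(5.0, 95.0, 5.0))
        fwd = neuro.modulation_index(spikes, events, recording_span=(0, 100))
        # swapping pre/post is equivalent to time-reversing the spike train
        rev = SpikeTrain(unit_id=0, spike_times=np.sort(100.0 - spikes.spike_times))
        rev_events = EventTable(times=np.sort(100.0 - events.times))
        bwd = neuro.modulation_index(rev, rev_events, recording_span=(0, 100))
        assert fwd.mi == pytest.approx(-bwd.mi, abs=1e-12)
        assert -1.0 <= fwd.mi <= 1.0


class TestSplitByEyePredictability:
    def _trace(self, vec, rate=100.0, n=150, onset_i=50, peak_off=5):
        # displacement rises to `vec` shortly after the onset sample and
        # falls back: a clear early extremum in both components
        vals = np.zeros((2, n))
        bump = np.exp(-0.5 * ((np.arange(n) - (onset_i + peak_off)) / 2.0) ** 2)
        vals[0] = vec[0] * bump
        vals[1] = vec[1] * bump
        return TimeSeries(times=np.arange(n) / rate, values=vals, rate=rate)

    def test_equal_vectors_predictable(self):
        onsets = EventTable(times=np.array([0.5]))
        m = self._trace((3.0, 1.0))
        pred, other, excl = neuro.split_by_eye_predictability(onsets, m, m)
        assert len(pred) == 1 and len(other) == 0 and excl == 0

    def test_orthogonal_vectors_other(self):
        onsets = EventTable(times=np.array([0.5]))
        m = self._trace((3.0, 0.0))
        p = self._trace((0.0, 3.0))
        pred, other, _ = neuro.split_by_eye_predictability(onsets, m, p)
        assert len(pred) == 0 and len(other) == 1

    def test_antipodal_vectors_other(self):
        onsets = EventTable(times=np.array([0.5]))
        m = self._trace((3.0, 1.0))
        p = self._trace((-3.0, -1.0))
        pred, other, _ = neuro.split_by_eye_predictability(onsets, m, p)
        assert len(pred) == 0 and len(other) == 1

    def test_no_extremum_excluded(self):
        onsets = EventTable(times=np.array([0.5]))
        # monotone ramp: no local extremum within the window
        n = 150
        vals = np.vstack([np.arange(n, dtype=float), np.zeros(n)])
        m = TimeSeries(times=np.arange(n) / 100.0, values=vals, rate=100.0)
        pred, other, excl = neuro.split_by_eye_predictability(onsets, m, m)
        assert excl == 1 and len(pred) == 0 and len(other) == 0
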