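"""Coherence estimators, cross-correlation lags and the noise simulation."""

import numpy as np
import pytest

from lfpvc import (
    RecordingSession,
    build_hypnogram,
    burst_triggered_coherence,
    coherence_vs_noise,
    default_montage,
    fit_sech,
    imag_coherence,
    lag_distribution,
    msc,
    state_coherence,
    xcorr_peak,
)
from lfpvc.connectivity import random_windows
from lfpvc.simulate import CHANNEL_LABELS


def _direct_msc(x, y, nperseg):
    """Independent oracle: explicit disjoint-segment FFT averaging."""
    m = len(x) // nperseg
    xs = x[: m * nperseg].reshape(m, nperseg)
    ys = y[: m * nperseg].reshape(m, nperseg)
    fx = np.fft.rfft(xs - xs.mean(axis=1, keepdims=True))
    fy = np.fft.rfft(ys - ys.mean(axis=1, keepdims=True))
    sxy = (fx * np.conj(fy)).mean(axis=0)
    sxx = (np.abs(fx) ** 2).mean(axis=0)
    syy = (np.abs(fy) ** 2).mean(axis=0)
    return np.abs(sxy) ** 2 / (sxx * syy)


class TestMsc:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(8192)
        spec = msc(x, x, nperseg=512)
        assert np.allclose(spec.values, 1.0, atol=1e-10)

    def test_independent_noise_bias_is_one_over_m(self, rng):
        m = 64
        x = rng.standard_normal(m * 256)
        y = rng.standard_normal(m * 256)
        spec = msc(x, y, nperseg=256, noverlap=0, window="boxcar")
        # known estimator bias: E[C] ~ 1/M for independent signals
        assert spec.values[5:-5].mean() == pytest.approx(1.0 / m, rel=0.35)

    def test_matches_direct_fft_oracle(self, rng):
        x = rng.standard_normal(40 * 256)
        y = 0.6 * x + rng.standard_normal(len(x))
        mine = msc(x, y, nperseg=256, noverlap=0, window="boxcar", detrend="constant")
        oracle = _direct_msc(x, y, 256)
        assert np.allclose(mine.values[1:-1], oracle[1:-1], atol=1e-8)

    def test_on_bin_sine_at_unit_per_bin_snr(self):
        # unit sine on bin 50 of 400-sample segments + SD-10 noise: the
        # per-bin SNR is 1, so coherence at the sine bin is 1/2
        rng = np.random.default_rng(7)
        n = 400 * 2000
        x = np.sin(2 * np.pi * 50 / 400 * np.arange(n))
        y = x + rng.normal(0, 10.0, n)
        spec = msc(x, y, nperseg=400, noverlap=0, window="boxcar")
        assert spec.at(50 / 400) == pytest.approx(0.5, abs=0.05)

    def test_symmetry_and_scale_invariance(self, rng):
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096) + 0.5 * x
        a = msc(x, y, nperseg=512)
        b = msc(y, x, nperseg=512)
        c = msc(3.7 * x, -0.2 * y, nperseg=512)
        assert np.allclose(a.values, b.values, atol=1e-12)
        assert np.allclose(a.values, c.values, atol=1e-10)
        assert np.all((a.values >= 0) & (a.values <= 1 + 1e-12))

    def test_single_segment_rejected(self, rng):
        x = rng.standard_normal(500)
        with pytest.raises(ValueError, match="segment"):
            msc(x, x, nperseg=400, noverlap=0)


class TestImagCoherence:
    def test_zero_lag_mixture_vanishes(self, rng):
        m = 100
        x = rng.standard_normal(m * 256)
        y = 2.5 * x  # instantaneous (volume-conduction-like) mixture
        spec = imag_coherence(x, y, nperseg=256, noverlap=0)
        assert np.all(spec.values < 3.0 / np.sqrt(m))

    def test_pure_delay_phase_law(self, rng):
        # y = x delayed by d: coherency magnitude ~1 and IC ~ |sin(2 pi f d)|
        fs, d_samp = 1000.0, 8
        mother = rng.standard_normal(300_000 + d_samp)
        x = mother[d_samp:]
        y = mother[:-d_samp] if d_samp else mother
        ic = imag_coherence(x, y, fs=fs, nperseg=500, noverlap=0)
        d = d_samp / fs
        expected = np.abs(np.sin(2 * np.pi * ic.frequencies * d))
        sel = (ic.frequencies > 5) & (ic.frequencies < 450)
        assert np.mean(np.abs(ic.values[sel] - expected[sel])) < 0.05

    def test_common_distal_source_suppressed_on_session(self, small_session):
        # the referential pair shares the strong distal source: high
        # magnitude-squared coherence at low frequency, damped imaginary part
        ms = state_coherence(small_session, "REM", "RR")
        ic = state_coherence(small_session, "REM", "RR", variant="imaginary")
        assert ms.at(1.0) > 0.5
        assert ic.at(1.0) < 0.2 * ms.at(1.0)


class TestXcorrPeak:
    def test_identity(self, rng):
        x = rng.standard_normal(2000)
        corr, lag = xcorr_peak(x, x, fs=1000.0)
        assert corr == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_integer_delay_recovered_exactly(self, rng):
        fs, d = 1000.0, 35
        mother = rng.standard_normal(5000 + d)
        x = mother[d:]
        y = mother[:-d]  # y lags x by d samples
        corr, lag = xcorr_peak(x, y, fs=fs, max_lag=0.2)
        assert lag == pytest.approx(d / fs)
        assert corr > 0.95

    def test_circular_shift_perfect_correlation(self, rng):
        for d in (1, 17, 35, 250):
            x = rng.standard_normal(4000)
            y = np.roll(x, d)
            corr, lag = xcorr_peak(x, y, fs=1.0, circular=True)
            assert abs(corr - 1.0) < 1e-12
            assert lag == d

    def test_anticorrelated_pair_signed_peak(self, rng):
        # brute-force oracle over all lags
        x = rng.standard_normal(600)
        y = -np.roll(x, 3)
        corr, lag = xcorr_peak(x, y, fs=1.0, max_lag=50, circular=True)
        n = len(x)
        xc, yc = x - x.mean(), y - y.mean()
        brute = {
            k: np.dot(np.roll(yc, -k), xc) / (n * x.std() * y.std())
            for k in range(-50, 51)
        }
        k_best = max(brute, key=lambda k: abs(brute[k]))
        assert lag == k_best == 3
        assert corr == pytest.approx(brute[k_best], abs=1e-9)
        assert corr < -0.95

    def test_maximum_convention_ignores_antiphase_peak(self):
        # narrow-band packets: |r| peaks ambiguously at the anti-phase lag
        # half a period away; the maximum-correlation convention does not
        fs = 1000.0
        t = np.arange(int(1.0 * fs)) / fs
        burst = np.hanning(len(t)) * np.sin(2 * np.pi * 12.0 * t)
        d = 35
        x = np.concatenate([burst, np.zeros(d)])
        y = np.concatenate([np.zeros(d), burst])
        _, lag = xcorr_peak(x, y, fs=fs, max_lag=0.1, peak="max")
        assert lag == pytest.approx(d / fs)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            xcorr_peak(np.zeros(100), np.ones(100), fs=1.0)


def _session_with_event_delays(delays_ms, fs=1000.0, seed=0):
    """Minimal session: one 12 Hz packet per event in CA1_e1, the PFC_e1
    copy shifted by the given per-event delay."""
    rng = np.random.default_rng(seed)
    n_events = len(delays_ms)
    epoch = 15.0
    hyp = build_hypnogram({"REM": n_events}, epoch_length=epoch, seed=0)
    n = int(hyp.duration * fs)
    data = np.zeros((len(CHANNEL_LABELS), n))
    data[0] = 1e-6 * rng.standard_normal(n)
    data[2] = 1e-6 * rng.standard_normal(n)
    bursts = []
    t = np.arange(int(0.8 * fs)) / fs
    packet = np.hanning(len(t)) * np.sin(2 * np.pi * 12.0 * t)
    from lfpvc import BurstSpec

    for k, d_ms in enumerate(delays_ms):
        onset = k * epoch + 5.0
        i = int(onset * fs)
        data[0, i:i + len(packet)] += 100e-6 * packet
        j = i + int(round(d_ms * fs / 1000.0))
        data[2, j:j + len(packet)] += 100e-6 * packet
        bursts.append(BurstSpec(onset, 0.8, 12.0, ("CA1", "PFC"), d_ms / 1e3))
    return RecordingSession(data, CHANNEL_LABELS, fs, default_montage(), hyp,
                            bursts=bursts)


class TestLagDistribution:
    def test_recovers_constant_delay(self):
        ses = _session_with_event_delays([35] * 12)
        dist = lag_distribution(ses, mode="DR")
        assert dist.median == pytest.approx(0.035, abs=1e-3)
        assert not dist.low_confidence

    def test_symmetric_delays_have_zero_median(self):
        delays = [-20, -12, -6, -2, 0, 0, 2, 6, 12, 20]
        dist = lag_distribution(_session_with_event_delays(delays), mode="DR")
        assert abs(dist.median) <= 2e-3

    def test_cdf_monotone_and_median_crossing(self):
        ses = _session_with_event_delays([10, 20, 30, 35, 35, 35, 40, 50, 60, 70])
        dist = lag_distribution(ses, mode="DR")
        assert np.all(np.diff(dist.cdf) >= 0)
        assert dist.cdf[0] == 0.0 and dist.cdf[-1] == 1.0
        # the sample median is the 50% crossing of the empirical CDF
        crossing = dist.grid[np.searchsorted(dist.cdf, 0.5)]
        assert crossing == pytest.approx(dist.median, abs=2 * (dist.grid[1] - dist.grid[0]))
        assert np.all(np.abs(dist.correlations) <= 1.0)

    def test_few_events_flagged(self):
        ses = _session_with_event_delays([35] * 4)
        with pytest.warns(UserWarning, match="low-confidence"):
            dist = lag_distribution(ses, mode="DR")
        assert dist.low_confidence

    def test_dr_median_unbiased_over_seeds(self):
        # parameter recovery: the generator injects a 35 ms delay; the
        # DR-mode median estimate should be unbiased to within one sample
        from lfpvc import simulate_session

        errors = []
        for seed in range(3):
            ses = simulate_session({"REM": 10}, seed=seed)
            dist = lag_distribution(ses, mode="DR")
            errors.append(dist.median - 0.035)
        assert abs(np.mean(errors)) < 1e-3


class TestBurstTriggeredCoherence:
    def test_trigger_area_swap_invariance(self, small_session):
        from lfpvc import detect_bursts

        fs = small_session.fs
        mask = small_session.hypnogram.state_mask("REM", fs, small_session.n_samples)
        ev_ca1 = detect_bursts(small_session.dr("CA1"), fs, mask=mask)
        ev_pfc = detect_bursts(small_session.dr("PFC"), fs, mask=mask)
        a = burst_triggered_coherence(small_session, ev_ca1, "CA1")
        b = burst_triggered_coherence(small_session, ev_pfc, "PFC")
        assert abs(a.band_mean(10, 14) - b.band_mean(10, 14)) < 0.1

    def test_events_beat_random_windows(self, small_session):
        events = small_session.common_bursts()
        triggered = burst_triggered_coherence(small_session, events)
        control = burst_triggered_coherence(
            small_session,
            random_windows(small_session, len(events), "REM", seed=99),
        )
        sliding = state_coherence(small_session, "REM", "DR")
        assert triggered.band_mean(10, 14) > control.band_mean(10, 14)
        assert triggered.band_mean(10, 14) > sliding.band_mean(10, 14)

    def test_too_few_events_rejected(self, small_session):
        with pytest.raises(ValueError, match="events"):
            burst_triggered_coherence(small_session, [(10.0, 10.8)])


class TestCoherenceVsNoise:
    def test_monotone_decreasing(self):
        curve = coherence_vs_noise([3.0, 10.0, 25.0], n_segments=600, seed=4)
        c = curve["coherence"].to_numpy()
        assert c[0] > c[1] > c[2]

    def test_nonpositive_levels_rejected(self):
        with pytest.raises(ValueError):
            coherence_vs_noise([0.0, 10.0])

    def test_segment_floor_enforced(self):
        with pytest.raises(ValueError, match="segments"):
            coherence_vs_noise([10.0], n_segments=100)


class TestFitSech:
    def test_recovers_exact_parameter(self):
        import pandas as pd

        n = np.array([1.0, 4.0, 8.0, 12.0, 20.0, 30.0])
        curve = pd.DataFrame({"snr_inv": n, "coherence": 1.0 / np.cosh(0.13 * n)})
        a, rms = fit_sech(curve)
        assert a == pytest.approx(0.13, abs=1e-6)
        assert rms < 1e-9

    def test_non_monotone_curve_warns(self):
        import pandas as pd

        curve = pd.DataFrame(
            {"snr_inv": [1.0, 5.0, 10.0], "coherence": [0.9, 0.3, 0.6]}
        )
        with pytest.warns(UserWarning, match="monotone"):
            fit_sech(curve)

    def test_too_few_points_rejected(self):
        import pandas as pd

        curve = pd.DataFrame({"snr_inv": [1.0, 2.0], "coherence": [0.9, 0.8]})
        with pytest.raises(ValueError):
            fit_sech(curve)
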