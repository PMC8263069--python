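import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstdyn.features import (burst_profiles, burst_rate_profile,
                               detect_bursts, envelope_pdf, find_spectral_peak,
                               hilbert_envelope, prepare_pair, psd,
                               segment_features, supra_threshold_runs, zscore)
from burstdyn.synthetic import gen_pink_noise
from burstdyn.types import Envelope, TimeSeries, DEFAULT_PERCENTILES

from conftest import brute_force_runs


class TestPreparePair:
    def test_sinusoid_peak_and_band(self):
        dt = 1e-3
        t = np.arange(60_000) * dt
        rng = np.random.default_rng(0)
        off = TimeSeries(np.sin(2 * np.pi * 25 * t) + 0.02 * rng.standard_normal(len(t)), dt)
        on = TimeSeries(0.5 * np.sin(2 * np.pi * 25 * t) + 0.02 * rng.standard_normal(len(t)), dt)
        f_on, f_off, peak = prepare_pair(on, off)
        assert peak == pytest.approx(25.0, abs=0.5)
        for ts in (f_on, f_off):
            assert ts.values.mean() == pytest.approx(0.0, abs=1e-9)
            assert ts.values.std() == pytest.approx(1.0, abs=1e-9)

    def test_filtered_noise_peak_recovered(self):
        # white noise band-passed at 20 +/- 3 Hz: detected peak near 20 Hz
        from burstdyn.features import bandpass_filter
        dt = 1e-3
        peaks = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ts = TimeSeries(rng.standard_normal(30_000), dt)
            filt = bandpass_filter(ts, 17.0, 23.0)
            peaks.append(find_spectral_peak(filt))
        assert abs(np.mean(peaks) - 20.0) < 0.5

    def test_no_peak_inside_band_is_error(self):
        # Brownian noise: PSD ~ 1/f^2 decays monotonically, so the in-band
        # maximum sits on the 13 Hz edge and no true peak exists
        rng = np.random.default_rng(2)
        ts = TimeSeries(np.cumsum(rng.standard_normal(30_000)), 1e-3)
        with pytest.raises(ValueError, match="no beta peak"):
            find_spectral_peak(ts)


class TestHilbertEnvelope:
    def test_cosine_amplitude(self):
        dt = 1e-3
        t = np.arange(10_000) * dt
        env = hilbert_envelope(TimeSeries(2.0 * np.cos(2 * np.pi * 20 * t), dt))
        core = env.values[500:-500]
        assert np.median(core) == pytest.approx(2.0, rel=0.01)

    def test_am_tone_tracks_modulator(self):
        dt = 1e-3
        t = np.arange(10_000) * dt
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        env = hilbert_envelope(TimeSeries(modulator * np.cos(2 * np.pi * 20 * t), dt))
        rmse = np.sqrt(np.mean((env.values[500:-500] - modulator[500:-500]) ** 2))
        assert rmse < 0.05

    def test_zero_signal(self):
        env = hilbert_envelope(TimeSeries(np.zeros(100), 1e-3))
        assert np.all(env.values == 0.0)


class TestDetectBursts:
    def test_all_zero_envelope(self):
        bs = detect_bursts(Envelope(np.zeros(50), 0.01), threshold=0.5)
        assert len(bs) == 0

    def test_hand_enumeration(self):
        env = Envelope(np.array([0, 1, 1, 1, 0, 1, 1, 0], float), 0.01)
        bs = detect_bursts(env, 0.5, min_duration=0.0)
        assert bs.durations.tolist() == pytest.approx([0.03, 0.02])
        assert np.mean(bs.durations) == pytest.approx(0.025)
        bs2 = detect_bursts(env, 0.5, min_duration=0.025)
        assert bs2.durations.tolist() == pytest.approx([0.03])

    def test_equals_brute_force_on_random_envelopes(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(2, 60)
            vals = rng.random(n)
            thr = rng.random()
            starts, ends = supra_threshold_runs(vals, thr)
            assert list(zip(starts, ends)) == brute_force_runs(vals, thr)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
           st.floats(0, 1))
    def test_run_conservation_property(self, values, threshold):
        # with no minimum duration, run lengths sum to the supra-threshold count
        vals = np.asarray(values)
        starts, ends = supra_threshold_runs(vals, threshold)
        assert (ends - starts).sum() == int(np.sum(vals > threshold))


class TestBurstProfiles:
    def test_hand_built_step_envelope(self):
        # three plateaus: durations at low threshold merge, at high split
        vals = np.concatenate([np.zeros(10), np.full(30, 1.0), np.zeros(10),
                               np.full(10, 2.0), np.zeros(10)])
        env = Envelope(vals, 0.01)
        prof = burst_profiles(env, np.array([0.3, 0.8]), min_duration=0.0)
        # 30% percentile threshold is below 1: bursts are the 30- and 10-runs
        assert prof.mean_duration[0] == pytest.approx(np.mean([0.30, 0.10]))
        # 80% percentile threshold equals 1: only the 2.0 plateau remains
        assert prof.mean_duration[1] == pytest.approx(0.10)
        assert prof.n_bursts.tolist() == [2, 1]

    def test_amplitude_exceeds_threshold(self, ou_envelope):
        prof = burst_profiles(ou_envelope, DEFAULT_PERCENTILES, min_duration=0.0)
        ok = np.isfinite(prof.mean_amplitude)
        assert np.all(prof.mean_amplitude[ok] >= prof.thresholds[ok])

    def test_degenerate_envelope_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            burst_profiles(Envelope(np.ones(100), 1e-3))

    def test_missing_marker_not_zero(self):
        # narrow spike: at high percentile + min_duration no burst qualifies
        vals = np.concatenate([np.random.default_rng(1).random(1000) * 0.1,
                               [5.0]])
        prof = burst_profiles(Envelope(vals, 1e-3), np.array([0.5, 0.99]),
                              min_duration=0.5)
        assert np.isnan(prof.mean_duration).all()
        assert (prof.n_bursts == 0).all()


class TestBurstRate:
    def test_hand_example(self):
        env = Envelope(np.array([0, 1, 1, 1, 0, 1, 1, 0], float), 0.01)
        prof = burst_profiles(env, np.array([0.3]), min_duration=0.0)
        # the 30th-percentile threshold falls strictly between 0 and 1
        assert prof.rate[0] == pytest.approx(2 / 0.08)

    def test_rate_duration_identity(self, ou_envelope):
        # rate * mean duration = fraction of samples above threshold, exactly
        prof = burst_profiles(ou_envelope, DEFAULT_PERCENTILES, min_duration=0.0)
        frac = np.array([(ou_envelope.values > t).mean() for t in prof.thresholds])
        assert np.allclose(prof.rate * prof.mean_duration, frac, atol=1e-12)
        # and equals (1 - percentile rank) up to ties at the threshold value
        assert np.allclose(frac, 1 - prof.percentiles, atol=1e-3)

    def test_rate_profile_wrapper(self, ou_envelope):
        rates = burst_rate_profile(ou_envelope, DEFAULT_PERCENTILES)
        assert rates.shape == DEFAULT_PERCENTILES.shape
        assert np.all(rates >= 0)


class TestEnvelopePDF:
    def test_uniform_density(self):
        rng = np.random.default_rng(5)
        pdf = envelope_pdf(Envelope(rng.random(1_000_000), 1e-3), n_bins=10)
        assert np.allclose(pdf.density, 1.0, rtol=0.03)

    def test_normalization_exact(self, ou_envelope):
        pdf = envelope_pdf(ou_envelope, n_bins=37)
        total = np.sum(pdf.density * np.diff(pdf.bin_edges))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_ou_envelope_matches_stationary_gaussian_at_mode(self, ou_envelope):
        # shifted OU: density at the mode ~ Gaussian(zeta^2/(2 theta)) peak
        pdf = envelope_pdf(ou_envelope, n_bins=60)
        peak = pdf.density.max()
        expected = 1.0 / np.sqrt(2 * np.pi * 0.5)  # sd^2 = 1/(2*1)
        assert peak == pytest.approx(expected, rel=0.05)


class TestPSD:
    def test_parseval_white_noise(self):
        rng = np.random.default_rng(3)
        ts = TimeSeries(rng.standard_normal(100_000), 1e-3)
        spec = psd(ts)
        integral = np.trapezoid(spec.power, spec.freqs)
        assert integral == pytest.approx(ts.values.var(), rel=0.05)

    def test_sinusoid_peak_and_positivity(self, beta_tone):
        spec = psd(beta_tone)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(20.0, abs=1.0)
        assert np.all(spec.power >= 0)


class TestSegmentFeatures:
    def test_segment_sizes(self):
        env = Envelope(np.random.default_rng(0).random(10_000), 1e-3)
        profs, pdfs = segment_features(env, n_segments=5, min_duration=0.0)
        assert len(profs) == len(pdfs) == 5

    def test_segment_means_close_to_whole(self, ou_envelope):
        profs, _ = segment_features(ou_envelope, n_segments=5, min_duration=0.0)
        seg_mean = np.nanmean([p.mean_duration for p in profs], axis=0)
        whole = burst_profiles(ou_envelope, DEFAULT_PERCENTILES, 0.0)
        sem = np.nanstd([p.mean_duration for p in profs], axis=0, ddof=1) / np.sqrt(5)
        ok = np.isfinite(seg_mean) & np.isfinite(whole.mean_duration)
        # agree within 3 SEM at (almost) all thresholds
        close = np.abs(seg_mean - whole.mean_duration)[ok] < 3 * sem[ok] + 1e-12
        assert close.mean() > 0.85


def test_pink_noise_spectrum_slope():
    ts = gen_pink_noise(200.0, 1e-3, seed=4)
    spec = psd(ts)
    mask = (spec.freqs >= 1) & (spec.freqs <= 100)
    slope = np.polyfit(np.log(spec.freqs[mask]), np.log(spec.power[mask]), 1)[0]
    assert -1.2 < slope < -0.8
    assert abs(ts.values.mean()) < 3 / np.sqrt(len(ts))
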