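import numpy as np
import pytest

from voltwave import synth
from voltwave.types import TwoChannelTrace
from voltwave.unmix import (
    artifact_band_power,
    detect_heartbeat,
    estimate_filter,
    regression_unmix,
    segment_spectra,
    select_parameters,
    unmix_movie,
    unmix_trace,
)


def _tone_trace(rate=1000.0, dur=20.0, f0=11.0, gain=0.7, lag=0.02,
                noise=1e-2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur * rate)) / rate
    phi = 0.3
    r = np.cos(2 * np.pi * f0 * t + phi) + noise * rng.standard_normal(len(t))
    g = gain * np.cos(2 * np.pi * f0 * (t - lag) + phi) \
        + noise * rng.standard_normal(len(t))
    return TwoChannelTrace(g, r, rate)


class TestSegmentation:
    def test_two_segments_without_overlap(self):
        trace = TwoChannelTrace(np.zeros(2000) + np.arange(2000),
                                np.ones(2000), 1000.0)
        assert segment_spectra(trace, 1.0, 0.0).n_segments == 2

    def test_segment_count_matches_enumeration(self):
        rng = np.random.default_rng(0)
        trace = TwoChannelTrace(rng.standard_normal(10000),
                                rng.standard_normal(10000), 1000.0)
        # starts every 0.25 s; enumerate: floor((10000-1000)/250)+1 = 37
        assert segment_spectra(trace, 1.0, 0.75).n_segments == 37

    def test_rectangular_window_bin_tone_is_single_bin(self):
        rate = 1000.0
        t = np.arange(2000) / rate
        x = np.cos(2 * np.pi * 5 * t)
        trace = TwoChannelTrace(x, x, rate)
        sp = segment_spectra(trace, 1.0, 0.0, window="boxcar")
        mag = np.abs(sp.g[0])
        assert np.argmax(mag) == 5
        mag5 = mag[5]
        mag[5] = 0
        assert mag.max() < 1e-9 * mag5

    def test_single_segment_rejected(self):
        trace = TwoChannelTrace(np.arange(100.0), np.ones(100), 100.0)
        with pytest.raises(ValueError):
            segment_spectra(trace, 1.0, 0.0)


class TestFilterEstimation:
    def test_duplicate_channels_give_unit_gain_impulse_kernel(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(8000)
        trace = TwoChannelTrace(x, x, 1000.0)
        filt = estimate_filter(segment_spectra(trace, 1.0, 0.75),
                               alpha=10.0, heart_hz=11.0)
        assert np.abs(filt.f[1:] - 1.0).max() < 1e-9
        # centered kernel ~ unit impulse at zero lag (the zeroed DC bin
        # removes exactly 1/n from the peak)
        assert filt.F_t[filt.kernel_center] == pytest.approx(1.0, abs=2e-3)

    def test_gain_and_delay_recovered_at_tone_bin(self):
        trace = _tone_trace(noise=1e-2)
        sp = segment_spectra(trace, 1.0, 0.75)
        filt = estimate_filter(sp, alpha=1.1, heart_hz=11.0)
        i = int(np.argmin(np.abs(sp.freqs_hz - 11.0)))
        expected = 0.7 * np.exp(-1j * 2 * np.pi * 11.0 * 0.02)
        assert abs(filt.f[i] - expected) < 1e-3

    def test_amplitude_limit_clips_magnitude_and_keeps_phase(self):
        rate = 1000.0
        t = np.arange(20000) / rate
        rng = np.random.default_rng(2)
        # strong coupling at 40 Hz (gain 10 with delay), weak at 11 Hz
        r = np.cos(2 * np.pi * 11 * t) + np.cos(2 * np.pi * 40 * t) \
            + 1e-3 * rng.standard_normal(len(t))
        g = np.cos(2 * np.pi * 11 * t) \
            + 10 * np.cos(2 * np.pi * 40 * (t - 0.005)) \
            + 1e-3 * rng.standard_normal(len(t))
        trace = TwoChannelTrace(g, r, rate)
        sp = segment_spectra(trace, 1.0, 0.75)
        filt = estimate_filter(sp, alpha=1.1, heart_hz=11.0)
        i11 = int(np.argmin(np.abs(sp.freqs_hz - 11.0)))
        i40 = int(np.argmin(np.abs(sp.freqs_hz - 40.0)))
        limit = 1.1 * np.abs(filt.f[i11])
        assert np.abs(filt.f[i40]) == pytest.approx(limit, rel=1e-6)
        expected_phase = np.angle(np.exp(-1j * 2 * np.pi * 40 * 0.005))
        assert np.angle(filt.f[i40]) == pytest.approx(expected_phase,
                                                      abs=0.02)

    def test_dc_gain_forced_to_zero(self):
        trace = _tone_trace()
        filt = estimate_filter(segment_spectra(trace, 1.0, 0.75),
                               heart_hz=11.0)
        assert filt.f[0] == 0.0


class TestHeartbeatDetection:
    def test_tone_in_pink_noise_found(self):
        rate = 500.0
        rng = np.random.default_rng(3)
        n = int(30 * rate)
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n)
        spec[1:] /= np.sqrt(f[1:])
        spec[0] = 0
        noise = np.fft.irfft(spec, n)
        noise /= noise.std()
        t = np.arange(n) / rate
        x = 2 * np.sin(2 * np.pi * 11 * t) + noise
        assert detect_heartbeat(x, rate) == pytest.approx(11.0, abs=0.3)

    def test_fundamental_preferred_over_harmonic(self):
        rate = 500.0
        t = np.arange(int(30 * rate)) / rate
        rng = np.random.default_rng(4)
        x = np.sin(2 * np.pi * 10 * t) + 1.2 * np.sin(2 * np.pi * 20 * t) \
            + 0.1 * rng.standard_normal(len(t))
        f = detect_heartbeat(x, rate, search_band_hz=(6.0, 25.0))
        assert f == pytest.approx(10.0, abs=0.3)

    def test_white_noise_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            detect_heartbeat(rng.standard_normal(10000), 1000.0)


class TestUnmixTrace:
    def test_reconstruction_is_exact(self, standard_trace):
        trace, _ = standard_trace
        res = unmix_trace(trace, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        recon = res.voltage + res.artifact_estimate
        assert np.abs(recon - trace.gevi).max() < 1e-12

    def test_pure_artifact_mostly_removed(self):
        rng = np.random.default_rng(6)
        r = rng.standard_normal(30000)
        trace = TwoChannelTrace(r.copy(), r, 1000.0)
        res = unmix_trace(trace, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        assert res.voltage.std() / trace.gevi.std() < 0.1

    def test_artifact_suppressed_voltage_preserved(self, standard_trace):
        trace, truth = standard_trace
        res = unmix_trace(trace, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        p_in = artifact_band_power(trace.gevi, 1000.0, 11.0, n_harmonics=2)
        p_out = artifact_band_power(res.voltage, 1000.0, 11.0, n_harmonics=2)
        assert 10 * np.log10(p_in / p_out) >= 20.0
        from voltwave.unmix import band_power
        pv = band_power(res.voltage, 1000.0, 30.0, 60.0)
        pv_true = band_power(truth.voltage, 1000.0, 30.0, 60.0)
        assert pv == pytest.approx(pv_true, rel=0.10)

    def test_beats_regression_when_phase_lag_nonzero(self, standard_trace):
        trace, _ = standard_trace
        res = unmix_trace(trace, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        reg = regression_unmix(trace)
        p_w = artifact_band_power(res.voltage, 1000.0, 11.0, n_harmonics=2)
        p_r = artifact_band_power(reg.voltage, 1000.0, 11.0, n_harmonics=2)
        assert p_w < p_r

    def test_noise_not_transferred_from_reference(self, white_noise_trace):
        res = unmix_trace(white_noise_trace, tau_s=1.0, alpha=1.1,
                          heart_hz=11.0)
        assert res.voltage.var() <= 1.05 * white_noise_trace.gevi.var()


class TestRegressionBaseline:
    def test_exact_scaling_recovered(self):
        rng = np.random.default_rng(7)
        r = rng.standard_normal(5000)
        trace = TwoChannelTrace(2.0 * r, r, 1000.0)
        res = regression_unmix(trace)
        assert res.residual_metrics["beta"] == pytest.approx(2.0)
        assert np.abs(res.voltage).max() < 1e-9

    def test_independent_channels_left_untouched(self):
        rng = np.random.default_rng(8)
        g = rng.standard_normal(50000)
        r = rng.standard_normal(50000)
        res = regression_unmix(TwoChannelTrace(g, r, 1000.0))
        assert abs(res.residual_metrics["beta"]) < 0.02
        assert np.corrcoef(res.voltage, g)[0, 1] > 0.999

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            regression_unmix(TwoChannelTrace(np.arange(10.0), np.ones(10),
                                             10.0))


class TestSelectParameters:
    def test_single_point_grid_returned(self, standard_trace):
        trace, _ = standard_trace
        tau, alpha, table = select_parameters(trace, [1.0], [1.1],
                                              heart_hz=11.0)
        assert (tau, alpha) == (1.0, 1.1)
        assert len(table) == 1

    def test_score_table_covers_grid(self, standard_trace):
        trace, _ = standard_trace
        _, _, table = select_parameters(trace, [1.0, 1.5], [1.0, 1.1, 1.2],
                                        heart_hz=11.0)
        assert len(table) == 6

    def test_empty_grid_rejected(self, standard_trace):
        trace, _ = standard_trace
        with pytest.raises(ValueError):
            select_parameters(trace, [], [1.1], heart_hz=11.0)

    def test_suppression_holds_across_recommended_grid(self, standard_trace):
        """Artifact suppression stays >= 20 dB at every (tau, alpha) in
        the recommended grid."""
        trace, _ = standard_trace
        p_in = artifact_band_power(trace.gevi, 1000.0, 11.0, n_harmonics=2)
        for tau in (1.0, 1.25, 1.5):
            for alpha in (1.0, 1.1, 1.2, 1.3):
                res = unmix_trace(trace, tau_s=tau, alpha=alpha,
                                  heart_hz=11.0)
                p_out = artifact_band_power(res.voltage, 1000.0, 11.0,
                                            n_harmonics=2)
                assert 10 * np.log10(p_in / p_out) >= 20.0


@pytest.fixture(scope="module")
def artifact_movie():
    art = synth.ArtifactSpec(
        heart_hz=11.0, n_harmonics=2, amp_gevi=(1.0, 0.5),
        amp_ref=(1.0, 0.5), phase_lag_s=(0.02, 0.02),
        slow_amp_gevi=0.0, slow_amp_ref=0.0,
        noise_sd_gevi=0.0, noise_sd_ref=0.0)
    wave = synth.PlaneWaveSpec(amplitude=1e-12)
    return synth.gen_movie(wave, artifact=art, shape=(3600, 16, 16),
                           rate_hz=300.0, pixel_pitch_mm=0.1, noise_sd=0.0,
                           seed=3)


class TestUnmixMovie:

    def test_uniform_artifact_suppressed_everywhere(self, artifact_movie):
        movie, _ = artifact_movie
        res = unmix_movie(movie, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        rms_in = movie.gevi.std(axis=0)
        rms_out = res.voltage.std(axis=0)
        assert (rms_out / rms_in).max() < 0.10

    def test_per_pixel_reconstruction(self, artifact_movie):
        movie, _ = artifact_movie
        res = unmix_movie(movie, tau_s=1.0, alpha=1.1, heart_hz=11.0)
        recon = res.voltage + res.artifact_estimate + res.prefilter_artifact
        assert np.abs(recon - movie.gevi).max() < 1e-10

    def test_large_prefilter_scale_equals_global_mean(self, artifact_movie):
        movie, _ = artifact_movie
        a = unmix_movie(movie, tau_s=1.0, alpha=1.1, heart_hz=11.0,
                        prefilter_scale_mm=1e6)
        b = unmix_movie(movie, tau_s=1.0, alpha=1.1, heart_hz=11.0,
                        prefilter_scale_mm=None)
        assert np.array_equal(a.prefilter_artifact, b.prefilter_artifact)
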