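"""Sensor path: kernel construction, filtering, deconvolution, calibration."""

import numpy as np
import pytest

from plumetrack import sensor

FS = 100.0
N = 3000  # one 30 s trial at 100 Hz


class TestBuildKernel:
    def test_shipped_defaults_are_valid(self):
        k = sensor.build_kernel(
            sensor.DEFAULT_TAU_RISE, sensor.DEFAULT_TAU_DECAY, FS, N
        )
        assert k.values[0] == 0.0
        assert k.values.sum() / FS == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("tau_rise,tau_decay", [(0.01, 0.3), (0.05, 1.5)])
    def test_normalization_and_zero_at_origin(self, tau_rise, tau_decay):
        k = sensor.build_kernel(tau_rise, tau_decay, FS, N)
        assert k.values[0] == pytest.approx(0.0, abs=1e-12)
        assert k.values.sum() * k.dt == pytest.approx(1.0, abs=1e-9)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            sensor.build_kernel(0.5, 0.4, FS, N)
        with pytest.raises(ValueError):
            sensor.build_kernel(0.0, 0.4, FS, N)

    def test_peak_time_matches_grid_argmax(self):
        # brute-force maximum of the raw double exponential on a fine grid
        tau_rise, tau_decay = 0.05, 0.4
        t = np.linspace(0, 3, 2_000_001)
        k0 = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
        t_star = sensor.kernel_peak_time(tau_rise, tau_decay)
        assert t[np.argmax(k0)] == pytest.approx(t_star, abs=1e-5)


class TestKaiserLowpass:
    t = np.arange(N) / FS

    def test_passband_tone_preserved(self):
        x = np.sin(2 * np.pi * 2.0 * self.t)
        y = sensor.kaiser_lowpass(x, FS)
        interior = slice(200, -200)
        assert np.abs(y[interior]).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated_40db(self):
        x = np.sin(2 * np.pi * 45.0 * self.t)
        y = sensor.kaiser_lowpass(x, FS)
        amp_in = np.abs(np.fft.rfft(x)).max()
        amp_out = np.abs(np.fft.rfft(y)).max()
        assert 20 * np.log10(amp_in / amp_out) >= 40.0

    def test_dc_unchanged(self):
        y = sensor.kaiser_lowpass(np.full(N, 3.7), FS)
        np.testing.assert_allclose(y, 3.7, rtol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sensor.kaiser_lowpass(np.zeros(N), FS, cutoff=60.0)

    def test_design_metadata_reports_attenuation(self):
        meta = sensor.kaiser_design_metadata(FS)
        assert meta["stopband_attenuation_db"] > 40.0
        assert meta["passband_ripple_db"] < 1.0


class TestNormalizeTrial:
    def test_window_stats_zero_one(self, rng):
        x = rng.normal(2.0, 3.0, N)
        w = slice(1000, 2000)
        y = sensor.normalize_trial(x, w)
        assert y[w].mean() == pytest.approx(0.0, abs=1e-9)
        assert y[w].std() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self, rng):
        x = rng.normal(size=N)
        w = slice(1000, 2000)
        once = sensor.normalize_trial(x, w)
        np.testing.assert_allclose(sensor.normalize_trial(once, w), once, atol=1e-12)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(sensor.DegenerateTrialError):
            sensor.normalize_trial(np.ones(N), slice(0, 100))


class TestFourierDeconvolve:
    def _interior_signal(self, rng):
        x = np.zeros(N)
        x[1200:1800] = rng.normal(1.0, 0.3, 600).cumsum() * 0.01
        x[1200:1800] += np.sin(2 * np.pi * 1.5 * np.arange(600) / FS)
        return x

    def test_round_trip_recovers_normalized_input(self, rng):
        k = sensor.build_kernel(0.0001, 0.4629, FS, N)
        x = self._interior_signal(rng)
        w = slice(1000, 2000)
        c = sensor.convolve_reference(x, k, window=w)
        d = sensor.fourier_deconvolve(c, k, window=w)
        x_norm = sensor.normalize_trial(x, w)
        err = np.linalg.norm(d - x_norm) / np.linalg.norm(x_norm)
        assert err < 1e-6

    def test_deconvolving_kernel_gives_impulse(self):
        k = sensor.build_kernel(0.001, 0.4629, FS, N)
        d = sensor.fourier_deconvolve(k.values.copy(), k)
        d = d - np.median(d)  # remove the normalization offset
        energy = d**2
        peak = int(np.argmax(energy))
        lo, hi = max(peak - 1, 0), peak + 2
        assert energy[lo:hi].sum() / energy.sum() >= 0.95

    def test_deconvolution_improves_reference_correlation(self, rng):
        # paired slow-sensor/fast-reference recording at calibration SNR:
        # deconvolving the sensor must increase correlation with the
        # reference (the motivation for the whole procedure)
        from plumetrack import synth

        timing = synth.TrialTiming()
        k = sensor.build_kernel(0.0001, 0.4629, FS, N)
        flow = synth.default_flow_presets()["high"]
        gains, gains_d = [], []
        for _ in range(5):
            conc = synth.simulate_concentration(flow, timing, rng)
            raw = synth.sensor_forward(conc, k, noise_sd=0.002, drift_scale=0.02, rng=rng)
            ref = conc + rng.normal(0, 0.01, N)
            w = timing.plume_slice(FS)
            m = timing.middle8_slice(FS)
            e = sensor.normalize_trial(sensor.kaiser_lowpass(raw, FS), w)
            d = sensor.fourier_deconvolve(e, k, window=w)
            p = sensor.normalize_trial(ref, w)
            gains.append(np.corrcoef(e[m], p[m])[0, 1])
            gains_d.append(np.corrcoef(d[m], p[m])[0, 1])
        assert np.mean(gains_d) > np.mean(gains)

    def test_all_zero_kernel_spectrum_rejected(self):
        k = sensor.build_kernel(0.01, 0.4, FS, N)
        object.__setattr__(k, "values", np.zeros(N))
        with pytest.raises(ValueError):
            sensor.fourier_deconvolve(np.ones(N), k)


class TestConvolveReference:
    def test_impulse_yields_normalized_kernel(self):
        k = sensor.build_kernel(0.01, 0.4, FS, N)
        p = np.zeros(N)
        p[0] = 1.0
        c = sensor.convolve_reference(p, k)
        k_norm = sensor.normalize_trial(k.values * k.dt, slice(None))
        np.testing.assert_allclose(c, k_norm, atol=1e-9)

    def test_output_lags_input(self, rng):
        from plumetrack import synth, tracking

        timing = synth.TrialTiming()
        k = sensor.build_kernel(0.0001, 0.4629, FS, N)
        conc = synth.simulate_concentration(
            synth.default_flow_presets()["high"], timing, rng
        )
        c = sensor.convolve_reference(conc, k)
        m = timing.middle8_slice(FS)
        lags, r = tracking.xcorr_trial(conc[m], c[m], max_lag=100)
        assert lags[np.nanargmax(r)] > 0


class TestCalibrateKernel:
    def _paired_trials(self, rng, tau_decay, n_trials=8, noise=0.001):
        from plumetrack import synth

        timing = synth.TrialTiming()
        k = sensor.build_kernel(0.0001, tau_decay, FS, N)
        flow = synth.default_flow_presets()["high"]
        p_trials, e_trials = [], []
        for _ in range(n_trials):
            conc = synth.simulate_concentration(flow, timing, rng)
            p_trials.append(conc + rng.normal(0, noise, N))
            e_trials.append(
                synth.sensor_forward(conc, k, noise_sd=noise, drift_scale=0.0, rng=rng)
            )
        return np.stack(e_trials), np.stack(p_trials), timing.plume_slice(FS)

    def test_recovers_decay_constant_within_one_grid_step(self, rng):
        tau_true = 0.4629
        e, p, w = self._paired_trials(rng, tau_true)
        res = sensor.calibrate_kernel(e, p, FS, w)
        assert sensor.recovery_within_one_step(
            res.tau_decay, tau_true, res.tau_decay_grid
        )

    def test_objective_minimal_at_truth_when_on_grid(self, rng):
        tau_rise_true, tau_decay_true = 0.001, 0.5
        grid_r = np.array([0.0005, 0.001, 0.002])
        grid_d = np.array([0.25, 0.5, 1.0])
        e, p, w = self._paired_trials(rng, tau_decay_true, noise=0.0)
        # rebuild e with the exact truth kernel, noise-free
        res = sensor.calibrate_kernel(
            e, p, FS, w, tau_rise_grid=grid_r, tau_decay_grid=grid_d
        )
        assert res.tau_decay == pytest.approx(tau_decay_true)

    def test_empty_grid_rejected(self, rng):
        e, p, w = self._paired_trials(rng, 0.4, n_trials=2)
        with pytest.raises(ValueError):
            sensor.calibrate_kernel(e, p, FS, w, tau_rise_grid=np.array([]))


class TestDownsampleToFrames:
    def test_printed_toy_vector(self):
        out = sensor.downsample_to_frames(np.array([1.0, 2, 3, 6, 6, 6]), 3.0, 1.0)
        np.testing.assert_allclose(out, [2.0, 6.0])

    def test_constant_preserved(self):
        out = sensor.downsample_to_frames(np.full(300, 2.5), FS, 30.0)
        np.testing.assert_allclose(out, 2.5)

    def test_mean_preserved_on_aligned_grids(self, rng):
        x = rng.normal(size=300)  # 300 = 10 frames of exactly 30 samples
        out = sensor.downsample_to_frames(x, 300.0, 10.0)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-6)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            sensor.downsample_to_frames(np.zeros(10), 10.0, 30.0)


def test_statistic_preservation_on_paired_session(rng):
    """Skewness/asymmetry of the deconvolved sensor track the fast
    reference along the bisector (orthogonal fit slope in [0.8, 1.2])."""
    from plumetrack import plume_stats, synth

    timing = synth.TrialTiming()
    k = sensor.build_kernel(0.0001, 0.4629, FS, N)
    presets = synth.default_flow_presets()
    pts = []
    for i in range(24):
        flow = presets["high"] if i % 2 else presets["low"]
        conc = synth.simulate_concentration(flow, timing, rng)
        raw = synth.sensor_forward(conc, k, noise_sd=0.002, drift_scale=0.02, rng=rng)
        ref = conc + rng.normal(0, 0.01, N)
        w, m = timing.plume_slice(FS), timing.middle8_slice(FS)
        e = sensor.normalize_trial(sensor.kaiser_lowpass(raw, FS), w)
        d = sensor.fourier_deconvolve(e, k, window=w)
        p = sensor.normalize_trial(ref, w)
        pts.append((plume_stats.skewness(p[m]), plume_stats.skewness(d[m])))
    pts = np.array(pts)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    slope = vt[0, 1] / vt[0, 0]
    assert 0.8 <= slope <= 1.2
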