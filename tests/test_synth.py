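"""Synthetic session generator: plume statistics, forward models, sessions."""

import dataclasses

import numpy as np
import pytest

from plumetrack import plume_stats, sensor, synth

FS = 100.0


class TestSimulateConcentration:
    def test_no_events_no_background_gives_zero(self, timing, presets, rng):
        flow = dataclasses.replace(
            presets["high"], whiff_rate=0.0, background_mean=0.0, noise_sd=0.0,
            rate_dispersion=None,
        )
        conc = synth.simulate_concentration(flow, timing, rng)
        np.testing.assert_array_equal(conc, 0.0)

    def test_zero_outside_plume_window_and_nonnegative(self, timing, presets, rng):
        conc = synth.simulate_concentration(presets["high"], timing, rng)
        w = timing.plume_slice(FS)
        assert conc.min() >= 0.0
        outside = np.ones(conc.size, dtype=bool)
        outside[w] = False
        np.testing.assert_array_equal(conc[outside], 0.0)

    def test_flow_presets_order_skewness(self, timing, presets):
        """High-flow plumes are more intermittent: mean skewness exceeds the
        low-flow mean by more than 0.5 over 20 plumes per condition."""
        sk = {}
        for lab in ("low", "high"):
            vals = [
                plume_stats.skewness(
                    synth.simulate_concentration(
                        presets[lab], timing, np.random.default_rng(300 + s)
                    )[timing.middle8_slice(FS)]
                )
                for s in range(20)
            ]
            sk[lab] = np.mean(vals)
        assert sk["high"] - sk["low"] > 0.5

    def test_amplitude_scale_doubles_mean(self, timing, presets):
        """Doubling the lognormal amplitude scale doubles the plume-window
        mean in expectation (linear superposition)."""
        base = dataclasses.replace(
            presets["high"], background_mean=0.0, noise_sd=0.0, rate_dispersion=None
        )
        doubled = dataclasses.replace(
            base, whiff_amplitude_mu=base.whiff_amplitude_mu + np.log(2.0)
        )
        w = timing.plume_slice(FS)
        m1 = np.mean([
            synth.simulate_concentration(base, timing, np.random.default_rng(s))[w].mean()
            for s in range(60)
        ])
        m2 = np.mean([
            synth.simulate_concentration(doubled, timing, np.random.default_rng(s))[w].mean()
            for s in range(60)
        ])
        assert m2 / m1 == pytest.approx(2.0, rel=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.FlowParams(
                label="high", whiff_rate=-1.0, whiff_duration_mu=0.0,
                whiff_duration_sigma=0.3, whiff_amplitude_mu=0.0,
                whiff_amplitude_sigma=0.3, background_mean=0.0,
                fluctuation_timescale=0.1,
            )
        with pytest.raises(ValueError):
            synth.FlowParams(
                label="sideways", whiff_rate=1.0, whiff_duration_mu=0.0,
                whiff_duration_sigma=0.3, whiff_amplitude_mu=0.0,
                whiff_amplitude_sigma=0.3, background_mean=0.0,
                fluctuation_timescale=0.1,
            )


class TestSensorForward:
    def test_impulse_response_proportional_to_kernel(self, timing, rng):
        k = sensor.build_kernel(0.01, 0.4, FS, timing.n_sensor)
        conc = np.zeros(timing.n_sensor)
        conc[500] = 1.0
        y = synth.sensor_forward(conc, k, noise_sd=0.0, drift_scale=0.0, rng=rng)
        np.testing.assert_allclose(y[500:], k.values[: y.size - 500] * k.dt, atol=1e-12)
        np.testing.assert_array_equal(y[:500], 0.0)

    def test_causal_peak_at_positive_lag(self, timing, presets, rng):
        from plumetrack import tracking

        k = sensor.build_kernel(0.0001, 0.4629, FS, timing.n_sensor)
        conc = synth.simulate_concentration(presets["high"], timing, rng)
        y = synth.sensor_forward(conc, k, noise_sd=0.0, drift_scale=0.0, rng=rng)
        m = timing.middle8_slice(FS)
        lags, r = tracking.xcorr_trial(conc[m], y[m], max_lag=100)
        assert lags[np.nanargmax(r)] > 0

    def test_mass_conserved_noise_free(self, timing, presets, rng):
        """With a unit-integral kernel and no noise/drift, total sensor mass
        over the trial equals total concentration mass within 1%."""
        k = sensor.build_kernel(0.0001, 0.4629, FS, timing.n_sensor)
        conc = synth.simulate_concentration(presets["low"], timing, rng)
        y = synth.sensor_forward(conc, k, noise_sd=0.0, drift_scale=0.0, rng=rng)
        assert y.sum() == pytest.approx(conc.sum(), rel=0.01)


class TestFluorescenceForward:
    def test_silent_glomerulus_is_flat_zero(self, timing, presets, rng):
        spec = synth.GlomerulusSpec(tracking_gain=0.0, tonic_gain=0.0, noise_sd=0.0)
        conc = synth.simulate_concentration(presets["high"], timing, rng)
        fluor, rate = synth.fluorescence_forward(conc, spec, timing, rng)
        np.testing.assert_array_equal(fluor, 0.0)
        np.testing.assert_array_equal(rate, 0.0)

    def test_rate_nonnegative_and_truth_returned(self, timing, presets, rng):
        spec = synth.GlomerulusSpec(tracking_gain=0.5, tonic_gain=0.1)
        conc = synth.simulate_concentration(presets["high"], timing, rng)
        fluor, rate = synth.fluorescence_forward(conc, spec, timing, rng)
        assert rate.min() >= 0.0
        assert fluor.shape == rate.shape == (timing.n_frames,)

    def test_tonic_only_is_responsive_but_not_tracking(self, timing, presets):
        """A purely tonic glomerulus responds to plume presence, yet its
        matched and trial-shuffled correlations with the concentration are
        statistically indistinguishable."""
        from plumetrack import tracking

        spec = synth.GlomerulusSpec(tracking_gain=0.0, tonic_gain=0.5, noise_sd=0.05)
        matched, shuffled = [], []
        e_all, c_all = [], []
        for s in range(20):
            rng = np.random.default_rng(800 + s)
            conc = synth.simulate_concentration(presets["high"], timing, rng)
            fluor, _ = synth.fluorescence_forward(conc, spec, timing, rng)
            m = timing.middle8_slice(timing.fs_imaging)
            e_all.append(sensor.downsample_to_frames(conc, FS, 30.0)[m])
            c_all.append(fluor[m])
        e_all, c_all = np.stack(e_all), np.stack(c_all)
        R = tracking.pairwise_correlograms(e_all, c_all, max_lag=15)
        n = R.shape[0]
        matched = R[np.arange(n), np.arange(n), :]
        r_match = tracking.aggregate_rg(matched, 15, 30.0)[0]
        null = tracking.bootstrap_null(
            R, 15, 30.0, n_boot=500, rng=np.random.default_rng(9)
        )
        assert null.ci[0] <= r_match <= null.ci[1]

        # plume presence does drive the trace: mean response >> baseline
        fluor, _ = synth.fluorescence_forward(
            synth.simulate_concentration(presets["high"], timing, np.random.default_rng(5)),
            spec, timing, np.random.default_rng(6),
        )
        base = fluor[timing.baseline_slice(30.0)]
        assert fluor[timing.plume_slice(30.0)].mean() > base.mean() + 3 * base.std()


class TestRenderMovie:
    def _specs(self, n=2):
        return synth.default_glomerulus_population(n, frame_size=(24, 24))

    def test_single_glomerulus_frames_proportional_to_mask(self, rng):
        specs = self._specs(1)
        traces = np.array([[1.0, 2.0, 0.5]])
        movie = synth.render_movie(specs, traces, (24, 24), 0.0, 0.0, rng)
        for t, v in enumerate(traces[0]):
            np.testing.assert_allclose(movie[t][specs[0].mask], v)
            np.testing.assert_allclose(movie[t][~specs[0].mask], 0.0)

    def test_zero_traces_give_constant_background(self, rng):
        specs = self._specs(2)
        movie = synth.render_movie(specs, np.zeros((2, 5)), (24, 24), 0.7, 0.0, rng)
        np.testing.assert_allclose(movie, 0.7)

    def test_pixel_mean_tracks_trace_at_low_noise(self, rng):
        specs = self._specs(2)
        traces = rng.normal(1.0, 0.5, (2, 200))
        movie = synth.render_movie(specs, traces, (24, 24), 0.1, 0.001, rng)
        extracted = movie[:, specs[0].mask].mean(axis=1)
        assert np.corrcoef(extracted, traces[0])[0, 1] > 0.99

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            synth.render_movie(self._specs(2), np.zeros((3, 5)), (24, 24), 0, 0, rng)


class TestSimulateSession:
    def test_block_design(self):
        config = synth.SessionConfig(glomeruli=synth.default_glomerulus_population(2))
        labels = synth.simulate_session(config, seed=0).flow_labels
        assert labels[:10] == ["medium"] * 10
        rest = labels[10:]
        assert len(rest) == 30
        for b in range(6):
            block = set(rest[b * 5 : (b + 1) * 5])
            assert len(block) == 1
        assert [rest[b * 5] for b in range(6)] == ["high", "low"] * 3

    def test_deterministic_in_seed(self):
        config = synth.SessionConfig(
            n_trials=12, n_medium=2, glomeruli=synth.default_glomerulus_population(2)
        )
        b1 = synth.simulate_session(config, seed=77)
        b2 = synth.simulate_session(config, seed=77)
        np.testing.assert_array_equal(b1.conc, b2.conc)
        np.testing.assert_array_equal(b1.sensor, b2.sensor)
        np.testing.assert_array_equal(b1.fluor, b2.fluor)
        b3 = synth.simulate_session(config, seed=78)
        assert not np.array_equal(b1.conc, b3.conc)

    def test_onsets_jittered_within_two_seconds(self):
        config = synth.SessionConfig(glomeruli=synth.default_glomerulus_population(2))
        bundle = synth.simulate_session(config, seed=5)
        onsets = np.array([t.plume_onset for t in bundle.timings])
        assert np.all((onsets >= 8.0) & (onsets <= 12.0))
        assert onsets.std() > 0.1  # actually jittered

    def test_channel_lengths_consistent(self, small_session):
        t = small_session.config.timing
        assert small_session.conc.shape[1] == t.n_sensor
        assert small_session.fluor.shape[2] == t.n_frames

    def test_invalid_block_design_rejected(self):
        config = synth.SessionConfig(
            n_trials=13, glomeruli=synth.default_glomerulus_population(2)
        )
        with pytest.raises(ValueError):
            synth.simulate_session(config, seed=0)
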