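"""Self-validation computations: analytic references and recovery checks.

Each function recomputes, from scratch, one of the quantities the package's
correctness rests on: the Gaussian null calibration of the responsivity
rule, symmetric-distribution references for the intermittency statistics,
the deconvolution round trip, kernel-calibration recovery, tracking-gain
monotonicity and bootstrap-null calibration, spectral identities, the
cross-correlation oracle, and the directional flow contrasts on a default
synthetic session.  Used by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import metrics, pipeline, plume_stats, sensor, synth, tracking, traces

FS = 100.0
FSI = 30.0
MAX_LAG = 15


# ---------------------------------------------------------------------------
# 1. responsivity null calibration


def gaussian_exceedance(seed: int, n: int = 1_000_000) -> float:
    """Fraction of i.i.d. standard-normal samples with |z| > 1.96 (expect
    2 * (1 - Phi(1.96)) ~= 5.0%)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    return float(
        metrics.trial_events(z, slice(0, n)) / n
    )


def null_trial_flag_rate(
    seed: int, n_trials: int = 2000, n_window: int = 330
) -> tuple[float, float]:
    """(Monte-Carlo flag rate, binomial-tail oracle) for the per-trial
    responsive flag under an i.i.d. Gaussian null."""
    rng = np.random.default_rng(seed)
    w = slice(0, n_window)
    counts = np.array([
        metrics.trial_events(rng.standard_normal(n_window), w)
        for _ in range(n_trials)
    ])
    rate = metrics.responsivity(counts, n_window)
    p = 2 * sps.norm.sf(1.96)
    oracle = float(sps.binom.sf(metrics.event_threshold(n_window), n_window, p))
    return float(rate), oracle


# ---------------------------------------------------------------------------
# 2. symmetric reference and flow contrast


def gaussian_symmetry_stats(seed: int, n: int = 100_000) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    return plume_stats.skewness(x), plume_stats.asymmetry(x)


def skewness_contrast_wins(seed: int, n_pairs: int = 20) -> tuple[int, float]:
    """(pairs where high-flow skewness > low-flow skewness, mean difference)
    over seeded plume pairs with the shipped presets."""
    presets = synth.default_flow_presets()
    timing = synth.TrialTiming()
    ss = np.random.SeedSequence([seed, 2])
    wins, diffs = 0, []
    for child in ss.spawn(n_pairs):
        r1, r2 = (np.random.default_rng(c) for c in child.spawn(2))
        m = timing.middle8_slice(FS)
        sk_hi = plume_stats.skewness(
            synth.simulate_concentration(presets["high"], timing, r1)[m]
        )
        sk_lo = plume_stats.skewness(
            synth.simulate_concentration(presets["low"], timing, r2)[m]
        )
        wins += sk_hi > sk_lo
        diffs.append(sk_hi - sk_lo)
    return wins, float(np.mean(diffs))


# ---------------------------------------------------------------------------
# 3. deconvolution round trip


def roundtrip_error(seed: int) -> float:
    """Relative L2 error of deconvolve(convolve(x)) for an interior-supported
    signal, noise-free."""
    rng = np.random.default_rng(seed)
    timing = synth.TrialTiming()
    n = timing.n_sensor
    k = sensor.build_kernel(
        sensor.DEFAULT_TAU_RISE, sensor.DEFAULT_TAU_DECAY, FS, n
    )
    x = np.zeros(n)
    seg = slice(1100, 1900)
    t = np.arange(800) / FS
    x[seg] = 1.0 + np.sin(2 * np.pi * 1.3 * t) + 0.3 * rng.standard_normal(800)
    w = timing.plume_slice(FS)
    c = sensor.convolve_reference(x, k, window=w)
    d = sensor.fourier_deconvolve(c, k, window=w)
    x_norm = sensor.normalize_trial(x, w)
    return float(np.linalg.norm(d - x_norm) / np.linalg.norm(x_norm))


# ---------------------------------------------------------------------------
# 4. kernel calibration recovery


def calibration_recovery_rate(
    seed: int, n_sessions: int = 10, n_trials: int = 10
) -> float:
    """Fraction of seeded paired sessions for which grid calibration lands
    within one grid step of the true decay constant."""
    timing = synth.TrialTiming()
    n = timing.n_sensor
    flow = synth.default_flow_presets()["high"]
    w = timing.plume_slice(FS)
    ss = np.random.SeedSequence([seed, 4])
    hits = 0
    for s, child in enumerate(ss.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        tau_true = float(rng.uniform(0.2, 1.0))
        k = sensor.build_kernel(0.0001, tau_true, FS, n)
        e_trials, p_trials = [], []
        for _ in range(n_trials):
            conc = synth.simulate_concentration(flow, timing, rng)
            p_trials.append(conc + rng.normal(0, 0.01, n))
            # the paired calibration rig is short and stable: drift is kept
            # an order of magnitude below the recording sessions'
            e_trials.append(
                synth.sensor_forward(conc, k, noise_sd=0.002, drift_scale=0.002, rng=rng)
            )
        res = sensor.calibrate_kernel(
            np.stack(e_trials), np.stack(p_trials), FS, w
        )
        hits += sensor.recovery_within_one_step(
            res.tau_decay, tau_true, res.tau_decay_grid
        )
    return hits / n_sessions


# ---------------------------------------------------------------------------
# 5. tracking recovery and null control


def _session_windows(spec, presets, timing, n_trials, seed_seq, flow="high"):
    e_tr, c_tr = [], []
    for child in seed_seq.spawn(n_trials):
        rng = np.random.default_rng(child)
        conc = synth.simulate_concentration(presets[flow], timing, rng)
        fluor, _ = synth.fluorescence_forward(conc, spec, timing, rng)
        m = timing.middle8_slice(FSI)
        e_tr.append(sensor.downsample_to_frames(conc, FS, FSI)[m])
        c_tr.append(traces.baseline_normalize(fluor, timing.baseline_slice(FSI))[m])
    return np.stack(e_tr), np.stack(c_tr)


def tracking_gain_curve(
    seed: int, gains=(0.0, 0.5, 1.0, 2.0), n_trials: int = 12
) -> list[float]:
    """r_g at each tracking gain (linear transfer, fixed plume seeds)."""
    presets = synth.default_flow_presets()
    timing = synth.TrialTiming()
    rgs = []
    for gain in gains:
        spec = synth.GlomerulusSpec(
            tracking_gain=gain, tonic_gain=0.2, noise_sd=0.3, saturation=None
        )
        ss = np.random.SeedSequence([seed, 5])  # same plumes for every gain
        e_tr, c_tr = _session_windows(spec, presets, timing, n_trials, ss)
        R = tracking.pairwise_correlograms(e_tr, c_tr, MAX_LAG)
        matched = R[np.arange(n_trials), np.arange(n_trials), :]
        rgs.append(tracking.aggregate_rg(matched, MAX_LAG, FSI)[0])
    return rgs


def bootstrap_false_flag_rate(
    seed: int, n_glomeruli: int = 200, n_trials: int = 40, n_boot: int = 2000
) -> float:
    """Two-sided outside-CI rate of the matched tracking statistic for
    tonic-only glomeruli (no dynamics coupling) under the bootstrap null."""
    presets = synth.default_flow_presets()
    timing = synth.TrialTiming()
    ss = np.random.SeedSequence([seed, 6])
    # shared plume set across glomeruli, as within one recording session
    plume_ss, glom_ss, boot_ss = ss.spawn(3)
    concs = []
    for child in plume_ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        concs.append(synth.simulate_concentration(presets["high"], timing, rng))
    m = timing.middle8_slice(FSI)
    e_tr = np.stack([sensor.downsample_to_frames(c, FS, FSI)[m] for c in concs])

    flags = 0
    boot_children = boot_ss.spawn(n_glomeruli)
    for g, child in enumerate(glom_ss.spawn(n_glomeruli)):
        rng = np.random.default_rng(child)
        spec = synth.GlomerulusSpec(
            tracking_gain=0.0,
            tonic_gain=float(rng.uniform(0.1, 0.5)),
            noise_sd=0.1,
        )
        c_tr = []
        for conc in concs:
            fluor, _ = synth.fluorescence_forward(conc, spec, timing, rng)
            c_tr.append(
                traces.baseline_normalize(fluor, timing.baseline_slice(FSI))[m]
            )
        c_tr = np.stack(c_tr)
        R = tracking.pairwise_correlograms(e_tr, c_tr, MAX_LAG)
        matched = R[np.arange(n_trials), np.arange(n_trials), :]
        r_g = tracking.aggregate_rg(matched, MAX_LAG, FSI)[0]
        null = tracking.bootstrap_null(
            R, MAX_LAG, FSI, n_boot=n_boot,
            rng=np.random.default_rng(boot_children[g]),
        )
        flags += not (null.ci[0] <= r_g <= null.ci[1])
    return flags / n_glomeruli


def lag_recovery_error(
    seed: int, response_lag: float = 0.13, n_trials: int = 20
) -> float:
    """Absolute error (frames) of the recovered argmax lag for a tracking
    glomerulus with a known response lag, through the full processing path
    (sensor deconvolution, baseline normalization, sparse deconvolution)."""
    presets = synth.default_flow_presets()
    timing = synth.TrialTiming()
    n = timing.n_sensor
    k = sensor.build_kernel(sensor.DEFAULT_TAU_RISE, sensor.DEFAULT_TAU_DECAY, FS, n)
    k30 = sensor.build_kernel(0.05, 0.4, FSI, timing.n_frames)
    spec = synth.GlomerulusSpec(
        tracking_gain=1.0, tonic_gain=0.1, response_lag=response_lag, noise_sd=0.05
    )
    ss = np.random.SeedSequence([seed, 7])
    e_tr, c_raw = [], []
    for child in ss.spawn(n_trials):
        rng = np.random.default_rng(child)
        conc = synth.simulate_concentration(presets["high"], timing, rng)
        raw = synth.sensor_forward(conc, k, noise_sd=0.002, drift_scale=0.02, rng=rng)
        w = timing.plume_slice(FS)
        e = sensor.normalize_trial(sensor.kaiser_lowpass(raw, FS), w)
        d = sensor.fourier_deconvolve(e, k, window=w)
        m = timing.middle8_slice(FSI)
        e_tr.append(sensor.downsample_to_frames(d, FS, FSI)[m])
        fluor, _ = synth.fluorescence_forward(conc, spec, timing, rng)
        c_raw.append(traces.baseline_normalize(fluor, timing.baseline_slice(FSI)))
    c_raw = np.stack(c_raw)
    lam, _ = traces.select_lambda([c_raw], k30, timing.baseline_slice(FSI))
    rate = traces.sparse_deconvolve(c_raw, lam, k30, tol=1e-6)
    m = timing.middle8_slice(FSI)
    c_tr = rate[:, m]
    e_tr = np.stack(e_tr)
    R = tracking.pairwise_correlograms(e_tr, c_tr, MAX_LAG)
    matched = R[np.arange(n_trials), np.arange(n_trials), :]
    _, lag_s = tracking.aggregate_rg(matched, MAX_LAG, FSI)
    return float(abs(lag_s * FSI - response_lag * FSI))


# ---------------------------------------------------------------------------
# 6/7. spectral identities and the cross-correlation oracle


def spectral_identities(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(900)
    spec = plume_stats.band_spectrum(x, FSI)
    t = np.arange(900) / FSI
    return {
        "parseval_error": float(abs(spec.power.sum() - x.var())),
        "band_fraction_2hz": plume_stats.band_spectrum(
            np.sin(2 * np.pi * 2 * t), FSI
        ).band_fraction,
        "band_fraction_10hz": plume_stats.band_spectrum(
            np.sin(2 * np.pi * 10 * t), FSI
        ).band_fraction,
    }


def xcorr_oracle_error(seed: int) -> float:
    """Max |difference| between xcorr_trial and per-lag Pearson coefficients
    computed by the direct moment formulas on toy 8-sample vectors."""
    rng = np.random.default_rng(seed)
    e = rng.random(8)
    c = rng.random(8)
    _, r = tracking.xcorr_trial(e, c, 1, min_overlap=0.5)
    worst = 0.0
    for lag in (-1, 0, 1):
        if lag >= 0:
            a, b = e[: 8 - lag], c[lag:]
        else:
            a, b = e[-lag:], c[: 8 + lag]
        am, bm = a - a.mean(), b - b.mean()
        expect = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        worst = max(worst, abs(r[1 + lag] - expect))
    return float(worst)


# ---------------------------------------------------------------------------
# 8. directional reproduction on a default session


def directional_session_results(seed: int, n_boot: int = 2000) -> dict:
    """Run the full pipeline on the default synthetic session and report the
    flow-contrast directions (population means per condition)."""
    config = pipeline.RunConfig(
        seed=seed,
        n_boot=n_boot,
        do_pca=False,
        session=synth.SessionConfig(),
    )
    res = pipeline.run_pipeline(config)
    mt = res.metrics_table.pivot(index="glomerulus", columns="condition")
    tt = res.tracking_table.pivot(
        index="glomerulus", columns="condition", values="r_g"
    )
    merged_resp = mt[("responsivity", "all")].to_numpy()
    rg_all = tt["all"].to_numpy()
    r_assoc = float(np.corrcoef(merged_resp, rg_all)[0, 1])
    return {
        "mean_response_low": float(mt[("mean_response", "low")].mean()),
        "mean_response_high": float(mt[("mean_response", "high")].mean()),
        "rg_low": float(tt["low"].mean()),
        "rg_high": float(tt["high"].mean()),
        "responsivity_low": float(mt[("responsivity", "low")].mean()),
        "responsivity_high": float(mt[("responsivity", "high")].mean()),
        "responsivity_tracking_r": r_assoc,
        "n_glomeruli": int(len(tt)),
    }
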