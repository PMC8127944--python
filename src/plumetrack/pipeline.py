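"""End-to-end orchestration and the session-level statistics report.

``run_pipeline`` chains the stages — simulate (or load), sensor
deconvolution, plume statistics, trace processing, tracking, response
metrics, optional pixel PCA — and writes every table as CSV carrying the
configuration hash.  ``stats_report`` recomputes the standard comparison
suite (paired t-tests, ANOVA + Tukey, KS, Pearson correlations) on the
session at hand; those statistics are session-specific by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io, metrics, pca, plume_stats, sensor, synth, tracking, traces

log = logging.getLogger("plumetrack")

CONDITIONS = ("all", "low", "high")


@dataclass
class RunConfig:
    """Pipeline configuration; threshold defaults are the analysis constants.

    merge_threshold 0.75 (ROI merge), event_z 1.96 (two-sided responsivity
    events), null_rate 0.05 (chance event fraction), lag_window_s 0.5
    (tracking lag window), band 0-5 Hz (response power), subset_percentile
    75 (strong-responder subset), n_boot 10,000 (bootstrap null).
    """

    seed: int = 0
    session: synth.SessionConfig = field(default_factory=synth.SessionConfig)
    merge_threshold: float = 0.75
    event_z: float = 1.96
    null_rate: float = 0.05
    lag_window_s: float = 0.5
    band: tuple[float, float] = (0.0, 5.0)
    subset_percentile: float = 75.0
    n_boot: int = 10_000
    deconv_tol: float = 1e-8
    deconv_max_iter: int = 4000
    do_pca: bool = True
    pca_components: int = 8
    do_tracking: bool = True
    do_metrics: bool = True


@dataclass
class SensorStage:
    """Deconvolved odor channel on both clocks plus per-trial windows."""

    d100: np.ndarray  # (n_trials, n_sensor) deconvolved, plume-normalized
    d30: np.ndarray  # (n_trials, n_frames)
    middle8_100: list[slice]
    middle8_30: list[slice]


def run_sensor_stage(bundle: synth.SessionBundle) -> SensorStage:
    """Kaiser low-pass, per-trial normalization, Fourier deconvolution and
    frame-averaged downsampling of the raw sensor channel."""
    timing = bundle.config.timing
    fs = timing.fs_sensor
    kernel = sensor.build_kernel(
        bundle.config.sensor_tau_rise, bundle.config.sensor_tau_decay,
        fs, timing.n_sensor,
    )
    d100 = np.zeros_like(bundle.sensor)
    d30 = np.zeros((bundle.n_trials, timing.n_frames))
    m100, m30 = [], []
    for i in range(bundle.n_trials):
        t = bundle.timings[i]
        plume = t.plume_slice(fs)
        filt = sensor.kaiser_lowpass(bundle.sensor[i], fs)
        e = sensor.normalize_trial(filt, plume)
        d100[i] = sensor.fourier_deconvolve(e, kernel, window=plume)
        d30[i] = sensor.downsample_to_frames(d100[i], fs, t.fs_imaging)
        m100.append(t.middle8_slice(fs))
        m30.append(t.middle8_slice(t.fs_imaging))
    return SensorStage(d100=d100, d30=d30, middle8_100=m100, middle8_30=m30)


@dataclass
class TraceStage:
    kept: list[int]
    merge_log: list[traces.MergeDecision]
    lambda_session: float
    lambda_per_glom: np.ndarray
    normalized: np.ndarray  # (n_trials, G_kept, n_frames)
    deconvolved: np.ndarray
    standardized: np.ndarray


def run_trace_stage(bundle: synth.SessionBundle, config: RunConfig) -> TraceStage:
    """Baseline-normalize, merge-screen, sparse-deconvolve and standardize."""
    timing = bundle.config.timing
    fsi = timing.fs_imaging
    n_tr, n_g = bundle.n_trials, bundle.n_glomeruli

    normalized = np.zeros_like(bundle.fluor)
    for i in range(n_tr):
        base = bundle.timings[i].baseline_slice(fsi)
        for g in range(n_g):
            normalized[i, g] = traces.baseline_normalize(bundle.fluor[i, g], base)

    baseline_concat = np.concatenate(
        [normalized[i, :, bundle.timings[i].baseline_slice(fsi)] for i in range(n_tr)],
        axis=1,
    )
    mean_activity = bundle.fluor.mean(axis=(0, 2))
    masks = [s.mask for s in bundle.config.glomeruli]
    adjacency = (
        traces.centroid_adjacency(masks) if all(m is not None for m in masks) else None
    )
    kept, merge_log = traces.merge_rois(
        baseline_concat, mean_activity, adjacency, config.merge_threshold
    )

    kernel30 = sensor.build_kernel(
        bundle.config.glomeruli[0].indicator_tau_rise,
        bundle.config.glomeruli[0].indicator_tau_decay,
        fsi, timing.n_frames,
    )
    base_slice = bundle.timings[0].baseline_slice(fsi)
    lam, lam_g = traces.select_lambda(
        [normalized[:, g, :] for g in kept], kernel30, base_slice,
        tol=max(config.deconv_tol, 1e-6), max_iter=config.deconv_max_iter,
    )

    deconv = np.zeros((n_tr, len(kept), timing.n_frames))
    standard = np.zeros_like(deconv)
    for gi, g in enumerate(kept):
        r = traces.sparse_deconvolve(
            normalized[:, g, :], lam, kernel30,
            tol=config.deconv_tol, max_iter=config.deconv_max_iter,
        )
        deconv[:, gi, :] = r
        sd = r.std()
        standard[:, gi, :] = r / sd if sd > 0 else r
    return TraceStage(
        kept=kept, merge_log=merge_log, lambda_session=lam,
        lambda_per_glom=lam_g, normalized=normalized[:, kept, :],
        deconvolved=deconv, standardized=standard,
    )


def run_tracking_stage(
    bundle: synth.SessionBundle,
    sensor_stage: SensorStage,
    trace_stage: TraceStage,
    config: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Tracking statistic r_g with shuffled and bootstrap nulls, per
    glomerulus and flow condition."""
    fsi = bundle.config.timing.fs_imaging
    max_lag = round(config.lag_window_s * fsi)
    rows = []
    e_wins = [sensor_stage.d30[i][sensor_stage.middle8_30[i]] for i in range(bundle.n_trials)]
    for gi in range(trace_stage.standardized.shape[1]):
        c_wins = [
            trace_stage.standardized[i, gi][sensor_stage.middle8_30[i]]
            for i in range(bundle.n_trials)
        ]
        n_min = min(w.size for w in e_wins)
        e_mat = np.stack([w[:n_min] for w in e_wins])
        c_mat = np.stack([w[:n_min] for w in c_wins])
        for cond in CONDITIONS:
            idx = bundle.trials_in(cond)
            if idx.size < 3:
                continue
            res = tracking.track_glomerulus(
                e_mat[idx], c_mat[idx], max_lag, fsi,
                n_boot=config.n_boot, rng=rng,
            )
            rows.append(
                {
                    "glomerulus": trace_stage.kept[gi],
                    "condition": cond,
                    "r_g": res.r_g,
                    "lag_s": res.lag_s,
                    "shuffled_r_g": res.shuffled_r_g,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "ci_lo": res.ci[0],
                    "ci_hi": res.ci[1],
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def run_metrics_stage(
    bundle: synth.SessionBundle,
    sensor_stage: SensorStage,
    trace_stage: TraceStage,
    config: RunConfig,
) -> pd.DataFrame:
    """Responsivity, mean response and 0-5 Hz power per glomerulus/condition.

    Events for responsivity are counted on the baseline-normalized stage,
    where the +/-1.96 baseline-band threshold keeps its chance calibration
    (the sparse deconvolution silences baselines outright, which would make
    the thresholded measure binary); mean response and band power use the
    standardized deconvolved stage.
    """
    fsi = bundle.config.timing.fs_imaging
    rows = []
    baselines = [t.baseline_slice(fsi) for t in bundle.timings]
    responses = [t.response_slice(fsi) for t in bundle.timings]
    plumes = [t.plume_slice(fsi) for t in bundle.timings]
    for gi in range(trace_stage.standardized.shape[1]):
        std_tr = trace_stage.standardized[:, gi, :]
        norm_tr = trace_stage.normalized[:, gi, :]
        events = np.array(
            [metrics.trial_events(norm_tr[i], responses[i], config.event_z)
             for i in range(bundle.n_trials)]
        )
        window_n = [norm_tr[i][responses[i]].size for i in range(bundle.n_trials)]
        power, frac = np.zeros(bundle.n_trials), np.zeros(bundle.n_trials)
        for i in range(bundle.n_trials):
            power[i], frac[i] = metrics.response_power_change(
                std_tr[i], baselines[i], plumes[i], fsi, config.band
            )
        for cond in CONDITIONS:
            idx = bundle.trials_in(cond)
            if idx.size == 0:
                continue
            resp = metrics.responsivity(
                events[idx], int(np.median([window_n[i] for i in idx])),
                config.null_rate,
            )
            mean_resp = float(
                np.mean([std_tr[i][sensor_stage.middle8_30[i]].mean() for i in idx])
            )
            rows.append(
                {
                    "glomerulus": trace_stage.kept[gi],
                    "condition": cond,
                    "responsivity": resp,
                    "mean_response": mean_resp,
                    "power_change_0_5": float(power[idx].mean()),
                    "band_fraction": float(frac[idx].mean()),
                }
            )
    return pd.DataFrame(rows)


def run_pca_stage(
    bundle: synth.SessionBundle,
    sensor_stage: SensorStage,
    config: RunConfig,
    rng: np.random.Generator,
) -> pd.DataFrame | None:
    """Per-trial pixel PCA on rendered movies for one low and one high trial."""
    specs = bundle.config.glomeruli
    if any(s.mask is None for s in specs):
        return None
    frame_size = specs[0].mask.shape
    rows = []
    fsi = bundle.config.timing.fs_imaging
    max_lag = round(config.lag_window_s * fsi)
    for cond in ("low", "high"):
        idx = bundle.trials_in(cond)
        if idx.size == 0:
            continue
        i = int(idx[0])
        movie = synth.render_movie(
            specs, bundle.fluor[i], frame_size,
            background=0.1, noise_sd=0.02, rng=rng,
        )
        mat = movie.reshape(movie.shape[0], -1).T
        res = pca.pca_decompose(mat, config.pca_components)
        corr, best = pca.component_odor_correlation(
            res.scores, sensor_stage.d30[i], max_lag
        )
        rows.append(
            {
                "trial": i,
                "condition": cond,
                "best_component": best,
                "best_correlation": float(corr[best]),
                "variance_explained_best": float(res.variance_explained[best]),
            }
        )
    return pd.DataFrame(rows)


def stats_report(
    plume_table: pd.DataFrame,
    tracking_table: pd.DataFrame | None,
    metrics_table: pd.DataFrame | None,
    raw_traces: np.ndarray | None = None,
    deconv_traces: np.ndarray | None = None,
    subset_percentile: float = 75.0,
) -> dict:
    """The comparison suite, recomputed on this session's tables.

    Reports raw per-test p-values.  Values depend on the session supplied;
    with fewer than 3 glomeruli the correlation entries are undefined.
    """
    report: dict = {}
    flows = plume_table["flow"].astype(str).to_numpy()
    if len(set(flows)) >= 2:
        for stat in ("skewness", "asymmetry"):
            cmp_res = plume_stats.compare_flows(plume_table[stat].to_numpy(), list(flows))
            report[f"anova_{stat}"] = {
                "F": cmp_res.f_statistic,
                "p": cmp_res.p_value,
                "pairwise": cmp_res.pairwise.to_dict("records"),
            }
    if tracking_table is not None and {"low", "high"} <= set(tracking_table["condition"]):
        piv = tracking_table.pivot(index="glomerulus", columns="condition", values="r_g")
        if {"low", "high"} <= set(piv.columns):
            delta, t, p = tracking.condition_contrast(
                piv["high"].to_numpy(), piv["low"].to_numpy()
            )
            report["tracking_high_vs_low"] = {
                "mean_delta": float(delta.mean()), "t": t, "p": p,
                "df": int(delta.size - 1),
            }
        sig = tracking_table.groupby("condition")["significant"].agg(["sum", "count"])
        report["significant_glomeruli"] = {
            cond: f"{int(row['sum'])}/{int(row['count'])}" for cond, row in sig.iterrows()
        }
    if metrics_table is not None:
        mpiv = metrics_table.pivot(
            index="glomerulus", columns="condition",
            values=["responsivity", "mean_response", "power_change_0_5"],
        )
        for name, col in (
            ("mean_response_low_vs_high", "mean_response"),
            ("responsivity_low_vs_high", "responsivity"),
        ):
            lo = mpiv[(col, "low")].to_numpy()
            hi = mpiv[(col, "high")].to_numpy()
            if np.allclose(lo, hi):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(lo, hi)
            report[name] = {
                "mean_delta": float(np.mean(lo - hi)), "t": float(t),
                "p": float(p), "df": int(lo.size - 1),
            }
        if tracking_table is not None:
            merged = metrics_table.merge(
                tracking_table[["glomerulus", "condition", "r_g"]],
                on=["glomerulus", "condition"],
            )
            sub = merged[merged["condition"] == "all"]
            if len(sub) >= 3:
                for col, name in (
                    ("responsivity", "responsivity_vs_tracking"),
                    ("power_change_0_5", "power_vs_tracking"),
                ):
                    if sub[col].std() == 0 or sub["r_g"].std() == 0:
                        report[name] = {"r": None, "p": None, "note": "degenerate"}
                    else:
                        r, p = sps.pearsonr(sub[col], sub["r_g"])
                        report[name] = {"r": float(r), "p": float(p)}
            else:
                report["responsivity_vs_tracking"] = {
                    "r": None, "p": None, "note": "fewer than 3 glomeruli",
                }
        try:
            subset = metrics.percentile_subset_contrast(
                mpiv[("mean_response", "all")].to_numpy(),
                mpiv[("power_change_0_5", "low")].to_numpy(),
                mpiv[("power_change_0_5", "high")].to_numpy(),
                subset_percentile,
            )
            report["power_subset_contrast"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in subset.items()
            }
        except ValueError as err:
            report["power_subset_contrast"] = {"note": str(err)}
    if raw_traces is not None and deconv_traces is not None and raw_traces.shape[0] >= 3:
        def _pairwise_corrs(mat):
            cm = np.corrcoef(mat)
            iu = np.triu_indices_from(cm, k=1)
            return cm[iu]

        raw_c = _pairwise_corrs(raw_traces)
        dec_c = _pairwise_corrs(deconv_traces)
        d_stat, p = sps.ks_2samp(raw_c, dec_c)
        report["ks_raw_vs_deconvolved_correlations"] = {
            "D": float(d_stat), "p": float(p),
            "raw_mean": float(np.nanmean(raw_c)),
            "deconvolved_mean": float(np.nanmean(dec_c)),
        }
    return report


@dataclass
class PipelineResult:
    bundle: synth.SessionBundle
    sensor_stage: SensorStage
    trace_stage: TraceStage
    plume_table: pd.DataFrame
    tracking_table: pd.DataFrame | None
    metrics_table: pd.DataFrame | None
    pca_table: pd.DataFrame | None
    report: dict


def run_pipeline(
    config: RunConfig,
    outdir: str | Path | None = None,
    bundle: synth.SessionBundle | None = None,
) -> PipelineResult:
    """Execute every enabled stage and (optionally) write artifacts.

    Deterministic in (config, bundle): rerunning with the same seed yields
    byte-identical CSV outputs.
    """
    ss = np.random.SeedSequence([config.seed, 0xA11CE])
    rng_boot, rng_pca = (np.random.default_rng(s) for s in ss.spawn(2))

    if bundle is None:
        log.info("simulating session (seed=%d)", config.seed)
        bundle = synth.simulate_session(config.session, config.seed)

    log.info("sensor deconvolution stage")
    sensor_stage = run_sensor_stage(bundle)

    fs = bundle.config.timing.fs_sensor
    windows = [
        sensor_stage.d100[i][sensor_stage.middle8_100[i]]
        for i in range(bundle.n_trials)
    ]
    plume_table = plume_stats.trial_stats_table(windows, bundle.flow_labels, fs)

    log.info("trace processing stage")
    trace_stage = run_trace_stage(bundle, config)

    tracking_table = None
    if config.do_tracking:
        log.info("tracking stage")
        tracking_table = run_tracking_stage(
            bundle, sensor_stage, trace_stage, config, rng_boot
        )
    metrics_table = None
    if config.do_metrics:
        log.info("metrics stage")
        metrics_table = run_metrics_stage(bundle, sensor_stage, trace_stage, config)

    pca_table = None
    if config.do_pca:
        log.info("PCA stage")
        pca_table = run_pca_stage(bundle, sensor_stage, config, rng_pca)

    raw_flat = bundle.fluor[:, trace_stage.kept, :].transpose(1, 0, 2).reshape(
        len(trace_stage.kept), -1
    )
    dec_flat = trace_stage.deconvolved.transpose(1, 0, 2).reshape(
        len(trace_stage.kept), -1
    )
    report = stats_report(
        plume_table, tracking_table, metrics_table,
        raw_traces=raw_flat, deconv_traces=dec_flat,
        subset_percentile=config.subset_percentile,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = io.config_hash(bundle.config)
        for name, table in (
            ("plume_stats", plume_table),
            ("tracking", tracking_table),
            ("metrics", metrics_table),
            ("pca", pca_table),
        ):
            if table is None:
                continue
            table = table.copy()
            table["config_hash"] = chash
            table.to_csv(outdir / f"{name}.csv", index=False)
        merge_rows = [
            {
                "roi_a": d.pair[0], "roi_b": d.pair[1],
                "baseline_correlation": d.baseline_correlation,
                "binarized_correlation": d.binarized_correlation,
                "dropped": d.dropped, "config_hash": chash,
            }
            for d in trace_stage.merge_log
        ]
        pd.DataFrame(merge_rows).to_csv(outdir / "merge_log.csv", index=False)
        with open(outdir / "stats_report.json", "w") as fh:
            json.dump({"config_hash": chash, "seed": config.seed, **report}, fh, indent=2)
        with open(outdir / "config.yaml", "w") as fh:
            fh.write(io.config_yaml(bundle.config))

    return PipelineResult(
        bundle=bundle,
        sensor_stage=sensor_stage,
        trace_stage=trace_stage,
        plume_table=plume_table,
        tracking_table=tracking_table,
        metrics_table=metrics_table,
        pca_table=pca_table,
        report=report,
    )
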