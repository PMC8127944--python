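"""Responsivity, mean response and 0-5 Hz response power across flows.

Counts threshold events (|z| > 1.96 of baseline) during plume + 1 s on the
baseline-normalized traces, flags trials whose event count beats the
chance expectation (ceil of 5% of window samples, strict), and measures
the mean deconvolved response and the 0-5 Hz band-power change from
baseline.  Expected pattern: higher mean response and responsivity in low
flow; power contrast emerging in the strongest responders (above the 75th
percentile); positive responsivity-tracking and power-tracking
associations.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from plumetrack import io, metrics, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    bundle = io.load_session(ROOT / "scratch" / "session.h5")
    sens = np.load(ROOT / "scratch" / "sensor_stage.npz")
    trc = np.load(ROOT / "scratch" / "trace_stage.npz")
    fsi = bundle.config.timing.fs_imaging
    sensor_stage = pipeline.SensorStage(
        d100=sens["d100"], d30=sens["d30"],
        middle8_100=[t.middle8_slice(100.0) for t in bundle.timings],
        middle8_30=[t.middle8_slice(fsi) for t in bundle.timings],
    )
    trace_stage = pipeline.TraceStage(
        kept=list(trc["kept"]), merge_log=[], lambda_session=np.nan,
        lambda_per_glom=np.array([]), normalized=trc["normalized"],
        deconvolved=trc["deconvolved"], standardized=trc["standardized"],
    )
    config = pipeline.RunConfig(seed=bundle.seed, session=bundle.config)

    table = pipeline.run_metrics_stage(bundle, sensor_stage, trace_stage, config)
    table["config_hash"] = io.config_hash(bundle.config)
    results = ROOT / "results"
    table.to_csv(results / "metrics.csv", index=False)

    piv = table.pivot(index="glomerulus", columns="condition")
    tracking_csv = results / "tracking.csv"
    report = {}
    for col, name in (("responsivity", "responsivity"), ("mean_response", "mean_response")):
        lo, hi = piv[(col, "low")], piv[(col, "high")]
        t, p = sps.ttest_rel(lo, hi)
        report[f"{name}_low_vs_high"] = {
            "low": float(lo.mean()), "high": float(hi.mean()),
            "t": float(t), "p": float(p), "df": int(len(lo) - 1),
        }
    subset = metrics.percentile_subset_contrast(
        piv[("mean_response", "all")].to_numpy(),
        piv[("power_change_0_5", "low")].to_numpy(),
        piv[("power_change_0_5", "high")].to_numpy(),
    )
    report["power_75th_percentile_contrast"] = {
        "n": subset["n"], "mean_delta": subset["mean_delta"],
        "t": subset["t"], "p": subset["p"],
    }
    if tracking_csv.exists():
        tt = pd.read_csv(tracking_csv)
        merged = table.merge(
            tt[["glomerulus", "condition", "r_g"]], on=["glomerulus", "condition"]
        )
        sub = merged[merged["condition"] == "all"]
        for col, name in (("responsivity", "responsivity_vs_tracking"),
                          ("power_change_0_5", "power_vs_tracking")):
            r, p = sps.pearsonr(sub[col], sub["r_g"])
            report[name] = {"r": float(r), "p": float(p)}
    with open(results / "response_metrics.json", "w") as fh:
        json.dump(report, fh, indent=2)

    for k, v in report.items():
        print(k, {kk: (round(vv, 3) if isinstance(vv, float) else vv)
                  for kk, vv in v.items()})


if __name__ == "__main__":
    main()
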