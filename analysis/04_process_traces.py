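"""Condition the glomerular traces: normalize, merge-screen, deconvolve.

Baseline-normalizes each trial by its 5 s pre-stimulus window, screens
neighboring ROIs for over-segmentation (drop when raw and binarized
baseline correlations both exceed 0.75), selects the session sparsity
penalty (median over per-glomerulus penalties that silence the baseline),
sparse-deconvolves every trace against the GCaMP6f indicator kernel, and
standardizes by each glomerulus's whole-trace SD.  Stages are cached for
the tracking and metrics scripts.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from plumetrack import io, pipeline

ROOT = Path(__file__).resolve().parents[1]


def main():
    bundle = io.load_session(ROOT / "scratch" / "session.h5")
    config = pipeline.RunConfig(seed=bundle.seed, session=bundle.config)
    stage = pipeline.run_trace_stage(bundle, config)

    np.savez_compressed(
        ROOT / "scratch" / "trace_stage.npz",
        kept=np.array(stage.kept),
        normalized=stage.normalized,
        deconvolved=stage.deconvolved,
        standardized=stage.standardized,
    )

    results = ROOT / "results"
    chash = io.config_hash(bundle.config)
    merge_rows = [
        {
            "roi_a": d.pair[0], "roi_b": d.pair[1],
            "baseline_correlation": d.baseline_correlation,
            "binarized_correlation": d.binarized_correlation,
            "dropped": d.dropped, "config_hash": chash,
        }
        for d in stage.merge_log
    ]
    pd.DataFrame(merge_rows).to_csv(results / "merge_log.csv", index=False)
    with open(results / "trace_processing.json", "w") as fh:
        json.dump(
            {
                "n_glomeruli_in": bundle.n_glomeruli,
                "n_glomeruli_kept": len(stage.kept),
                "lambda_session": stage.lambda_session,
                "lambda_per_glomerulus": stage.lambda_per_glom.tolist(),
                "config_hash": chash,
            },
            fh, indent=2,
        )

    print(f"kept {len(stage.kept)}/{bundle.n_glomeruli} glomeruli after merge screen")
    print(f"session lambda = {stage.lambda_session:.4f} "
          f"(per-glomerulus range {stage.lambda_per_glom.min():.4f}"
          f"-{stage.lambda_per_glom.max():.4f})")
    silent = np.mean(stage.deconvolved[:, :, :150] <= 1e-12)
    print(f"baseline frames silent after deconvolution: {silent:.1%}")


if __name__ == "__main__":
    main()
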