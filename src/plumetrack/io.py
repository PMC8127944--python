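"""Session container I/O: HDF5, long-format CSV, YAML configs, TIFF movies.

HDF5 layout: ``/trials/<i>/{concentration,sensor,reference,fluorescence,
truth}`` with per-trial attrs (flow, plume_onset) and root attrs for rates,
seed and the YAML-serialized config.  Glomerulus masks, when present, live
in ``/glomeruli/masks``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synth


def _flow_to_dict(fp: synth.FlowParams) -> dict:
    return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in dataclasses.asdict(fp).items()}


def config_to_dict(config: synth.SessionConfig) -> dict:
    d = {
        "n_trials": config.n_trials,
        "n_medium": config.n_medium,
        "block_size": config.block_size,
        "first_block": config.first_block,
        "timing": dataclasses.asdict(config.timing),
        "flow_presets": {k: _flow_to_dict(v) for k, v in config.flow_presets.items()},
        "glomeruli": [
            {
                k: (float(v) if isinstance(v, np.floating) else v)
                for k, v in dataclasses.asdict(g).items()
                if k != "mask"
            }
            | {"has_mask": g.mask is not None}
            for g in config.glomeruli
        ],
        "sensor_tau_rise": config.sensor_tau_rise,
        "sensor_tau_decay": config.sensor_tau_decay,
        "sensor_noise_sd": config.sensor_noise_sd,
        "sensor_drift_scale": config.sensor_drift_scale,
        "reference_noise_sd": config.reference_noise_sd,
        "with_reference": config.with_reference,
    }
    return d


def config_from_dict(d: dict, masks: list[np.ndarray | None] | None = None) -> synth.SessionConfig:
    gloms = []
    for i, g in enumerate(d["glomeruli"]):
        g = dict(g)
        g.pop("has_mask", None)
        mask = masks[i] if masks is not None else None
        gloms.append(synth.GlomerulusSpec(mask=mask, **g))
    return synth.SessionConfig(
        n_trials=d["n_trials"],
        n_medium=d["n_medium"],
        block_size=d["block_size"],
        first_block=d["first_block"],
        timing=synth.TrialTiming(**d["timing"]),
        flow_presets={k: synth.FlowParams(**v) for k, v in d["flow_presets"].items()},
        glomeruli=gloms,
        sensor_tau_rise=d["sensor_tau_rise"],
        sensor_tau_decay=d["sensor_tau_decay"],
        sensor_noise_sd=d["sensor_noise_sd"],
        sensor_drift_scale=d["sensor_drift_scale"],
        reference_noise_sd=d["reference_noise_sd"],
        with_reference=d["with_reference"],
    )


def config_yaml(config: synth.SessionConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=True)


def config_hash(config) -> str:
    """Short stable hash identifying a configuration in output tables."""
    if dataclasses.is_dataclass(config) and isinstance(config, synth.SessionConfig):
        text = config_yaml(config)
    else:
        text = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_session(bundle: synth.SessionBundle, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = bundle.seed
        f.attrs["fs_sensor"] = bundle.config.timing.fs_sensor
        f.attrs["fs_imaging"] = bundle.config.timing.fs_imaging
        f.attrs["config_yaml"] = config_yaml(bundle.config)
        trials = f.create_group("trials")
        for i in range(bundle.n_trials):
            g = trials.create_group(str(i))
            g.attrs["flow"] = bundle.flow_labels[i]
            g.attrs["plume_onset"] = bundle.timings[i].plume_onset
            g.create_dataset("concentration", data=bundle.conc[i])
            g.create_dataset("sensor", data=bundle.sensor[i])
            if bundle.reference is not None:
                g.create_dataset("reference", data=bundle.reference[i])
            g.create_dataset("fluorescence", data=bundle.fluor[i])
            g.create_dataset("truth", data=bundle.truth_rate[i])
        masks = [s.mask for s in bundle.config.glomeruli]
        if all(m is not None for m in masks) and masks:
            f.create_dataset("glomeruli/masks", data=np.stack(masks).astype(np.uint8))


def load_session(path: str | Path) -> synth.SessionBundle:
    with h5py.File(path, "r") as f:
        cfg_dict = yaml.safe_load(f.attrs["config_yaml"])
        masks = None
        if "glomeruli/masks" in f:
            masks = list(np.asarray(f["glomeruli/masks"]).astype(bool))
        config = config_from_dict(cfg_dict, masks)
        n = len(f["trials"])
        order = [str(i) for i in range(n)]
        flow_labels, timings = [], []
        conc, sensor, reference, fluor, truth = [], [], [], [], []
        has_ref = "reference" in f["trials"]["0"]
        for key in order:
            g = f["trials"][key]
            flow_labels.append(g.attrs["flow"])
            timings.append(
                dataclasses.replace(
                    config.timing, plume_onset=float(g.attrs["plume_onset"])
                )
            )
            conc.append(np.asarray(g["concentration"]))
            sensor.append(np.asarray(g["sensor"]))
            if has_ref:
                reference.append(np.asarray(g["reference"]))
            fluor.append(np.asarray(g["fluorescence"]))
            truth.append(np.asarray(g["truth"]))
        return synth.SessionBundle(
            config=config,
            seed=int(f.attrs["seed"]),
            flow_labels=flow_labels,
            timings=timings,
            conc=np.stack(conc),
            sensor=np.stack(sensor),
            reference=np.stack(reference) if has_ref else None,
            fluor=np.stack(fluor),
            truth_rate=np.stack(truth),
        )


def session_to_csv_long(bundle: synth.SessionBundle, path: str | Path) -> None:
    """Long-format export: trial, channel, time, value (sensor channels only;
    fluorescence is exported per glomerulus as fluor_g<g>)."""
    frames = []
    fs = bundle.config.timing.fs_sensor
    fsi = bundle.config.timing.fs_imaging
    t100 = np.arange(bundle.conc.shape[1]) / fs
    t30 = np.arange(bundle.fluor.shape[2]) / fsi
    for i in range(bundle.n_trials):
        channels = {"concentration": (t100, bundle.conc[i]), "sensor": (t100, bundle.sensor[i])}
        if bundle.reference is not None:
            channels["reference"] = (t100, bundle.reference[i])
        for g in range(bundle.n_glomeruli):
            channels[f"fluor_g{g}"] = (t30, bundle.fluor[i, g])
        for name, (t, v) in channels.items():
            frames.append(
                pd.DataFrame({"trial": i, "channel": name, "time": t, "value": v})
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_movie_tiff(movie: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
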