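"""Readers and writers for the pipeline's data products.

Populations, trial sets, and network parameters are stored in HDF5 (one
group per speed bin, with sampling rate, units, and seed recorded as
attributes); factor traces and summary tables export to CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import PopulationRates, Trial, TrialSet
from .rnn import RNNParams

__all__ = [
    "save_rates",
    "load_rates",
    "save_trials",
    "load_trials",
    "save_params",
    "load_params",
    "rates_to_csv",
    "write_json",
]


def save_rates(path, rates: PopulationRates) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["time_step_ms"] = rates.time_step
        f.attrs["kind"] = rates.kind
        f.attrs["units"] = "spikes/s" if rates.kind == "neural" else "normalized"
        if "spec" in rates.meta and hasattr(rates.meta["spec"], "seed"):
            f.attrs["seed"] = rates.meta["spec"].seed
        for s, (v, label) in enumerate(zip(rates.values, rates.speed_bins)):
            g = f.create_group(f"speed_{s:02d}")
            g.attrs["speed_bin"] = float(label)
            g.create_dataset("rates", data=v)


def load_rates(path) -> PopulationRates:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f.keys() if k.startswith("speed_"))
        values = [f[k]["rates"][()] for k in keys]
        labels = [float(f[k].attrs["speed_bin"]) for k in keys]
        return PopulationRates(
            values,
            time_step=float(f.attrs["time_step_ms"]),
            speed_bins=labels,
            kind=str(f.attrs["kind"]),
        )


def save_trials(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["time_step_ms"] = trials.time_step
        if "seed" in trials.meta:
            f.attrs["seed"] = trials.meta["seed"]
        for i, tr in enumerate(trials.trials):
            g = f.create_group(f"trial_{i:04d}")
            g.attrs["duration_ms"] = tr.duration
            g.attrs["speed_bin"] = tr.speed_bin
            g.attrs["is_spikes"] = tr.is_spikes
            g.create_dataset("traces", data=tr.traces)
            g.create_dataset("position", data=tr.position)


def load_trials(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        out = []
        for k in sorted(f.keys()):
            g = f[k]
            out.append(
                Trial(
                    traces=g["traces"][()],
                    duration=float(g.attrs["duration_ms"]),
                    position=g["position"][()],
                    speed_bin=int(g.attrs["speed_bin"]),
                    is_spikes=bool(g.attrs["is_spikes"]),
                )
            )
        return TrialSet(out, time_step=float(f.attrs["time_step_ms"]))


def save_params(path, params: RNNParams, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for name in ("A", "B", "b", "C", "d_out"):
            f.create_dataset(name, data=getattr(params, name))
        f.attrs["tau"] = params.tau
        f.attrs["dt"] = params.dt
        if config is not None:
            f.attrs["config_json"] = json.dumps(config, default=str)


def load_params(path) -> RNNParams:
    with h5py.File(path, "r") as f:
        return RNNParams(
            A=f["A"][()], B=f["B"][()], b=f["b"][()],
            C=f["C"][()], d_out=f["d_out"][()],
            tau=float(f.attrs["tau"]), dt=float(f.attrs["dt"]),
        )


def rates_to_csv(path, rates: PopulationRates) -> None:
    """Long-format CSV export of factor / rate traces."""
    frames = []
    for s, v in enumerate(rates.values):
        t = np.arange(v.shape[1]) * rates.time_step
        df = pd.DataFrame(v.T, columns=[f"unit_{u}" for u in range(v.shape[0])])
        df.insert(0, "time_ms", t)
        df.insert(0, "speed_bin", s)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
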