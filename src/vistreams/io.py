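"""HDF5 container for simulated (or imported) recordings.

Layout: ``/population`` holds the neuron metadata table column-wise,
``/schedules/<dataset>`` the presentation schedules, and
``/traces/<dataset>`` the (neurons x trials x frames) dF/F arrays with
the frame rate and calcium-kernel parameters as root attributes.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .synthetic import CalciumKernel, SimulatedDataset

__all__ = ["save_simulation", "load_simulation"]


def _write_frame(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype("S")
        group.create_dataset(col, data=data)
    group.attrs["columns"] = [str(c) for c in df.columns]


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    out = {}
    for col in cols:
        data = group[col][()]
        if data.dtype.kind == "S":
            data = data.astype(str)
        out[col] = data
    return pd.DataFrame(out)


def save_simulation(sim: SimulatedDataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        _write_frame(f.create_group("population"), sim.population)
        sched = f.create_group("schedules")
        for ds, df in sim.schedules.items():
            _write_frame(sched.create_group(str(ds)), df)
        traces = f.create_group("traces")
        for ds, arr in sim.traces.items():
            traces.create_dataset(str(ds), data=arr, compression="gzip",
                                  compression_opts=4)
        f.attrs["frame_rate"] = sim.frame_rate
        f.attrs["kernel_rise_ms"] = sim.kernel.rise_ms
        f.attrs["kernel_decay_ms"] = sim.kernel.decay_ms


def load_simulation(path: str) -> SimulatedDataset:
    with h5py.File(path, "r") as f:
        population = _read_frame(f["population"])
        schedules = {int(k): _read_frame(g)
                     for k, g in f["schedules"].items()}
        traces = {int(k): d[()] for k, d in f["traces"].items()}
        kernel = CalciumKernel(rise_ms=float(f.attrs["kernel_rise_ms"]),
                               decay_ms=float(f.attrs["kernel_decay_ms"]))
        frame_rate = float(f.attrs["frame_rate"])
    if "responsive" in population:
        population["responsive"] = population["responsive"].astype(bool)
    return SimulatedDataset(population=population, schedules=schedules,
                            traces=traces, frame_rate=frame_rate,
                            kernel=kernel)
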