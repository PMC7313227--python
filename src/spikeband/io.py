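"""CSV / HDF5 persistence for traces, spike trains and analysis outputs."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .traces import CurrentTrace, SpikeTrain, StimulusParams, VoltageTrace
from .transfer import STAResult, TransferFunction, TransferSummary

__all__ = [
    "save_current_csv", "load_current_csv",
    "save_voltage_csv", "load_voltage_csv",
    "save_stimulus_hdf5", "load_stimulus_hdf5",
    "save_sta_csv", "save_transfer_csv", "save_summary_json",
]


def save_current_csv(path, trace: CurrentTrace) -> None:
    pd.DataFrame({"time_ms": trace.times, "current_pA": trace.values}).to_csv(
        path, index=False)


def load_current_csv(path) -> CurrentTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return CurrentTrace(dt=dt, values=df["current_pA"].to_numpy())


def save_voltage_csv(path, trace: VoltageTrace) -> None:
    pd.DataFrame({"time_ms": trace.times, "voltage_mV": trace.values}).to_csv(
        path, index=False)


def load_voltage_csv(path) -> VoltageTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return VoltageTrace(dt=dt, values=df["voltage_mV"].to_numpy())


def save_stimulus_hdf5(path, trace: CurrentTrace, tau_corr: float | None = None,
                       seed: int | None = None) -> None:
    """Store a stimulus as an HDF5 group {dt, values, i0, sigma, tau_corr, seed}."""
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        g.attrs["dt"] = trace.dt
        g.create_dataset("values", data=trace.values)
        if trace.params is not None:
            g.attrs["i0"] = trace.params.i0
            g.attrs["sigma"] = trace.params.sigma
        if tau_corr is not None:
            g.attrs["tau_corr"] = tau_corr
        if seed is not None:
            g.attrs["seed"] = seed


def load_stimulus_hdf5(path) -> CurrentTrace:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        params = None
        if "i0" in g.attrs and "sigma" in g.attrs:
            params = StimulusParams(i0=float(g.attrs["i0"]),
                                    sigma=float(g.attrs["sigma"]))
        return CurrentTrace(dt=float(g.attrs["dt"]), values=g["values"][:],
                            params=params)


def save_sta_csv(path, sta: STAResult) -> None:
    pd.DataFrame({"lag_ms": sta.lags, "sta_pA": sta.values}).to_csv(path, index=False)


def save_transfer_csv(path, tf: TransferFunction) -> None:
    cols = {"freq_hz": tf.freqs, "magnitude": tf.magnitude}
    if tf.H is not None:
        cols["re"] = tf.H.real
        cols["im"] = tf.H.imag
    if tf.phase is not None:
        cols["phase"] = tf.phase
    if tf.threshold is not None:
        cols["threshold"] = tf.threshold
    pd.DataFrame(cols).to_csv(path, index=False)


def save_summary_json(path, summary: TransferSummary) -> None:
    d = asdict(summary)
    d["fit_range"] = list(np.asarray(d["fit_range"], dtype=float))
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
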