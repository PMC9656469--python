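"""File contracts: CSV/JSON (and optional HDF5) readers and writers.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header row.
Sweep files carry one row per sample (time_s, voltage_mV, sweep, current_pA);
patch files carry (time_s, current_pA, Vp_mV); fluorescence files carry
(time_s, F_au) with the perfusion protocol in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import FluoTrace
from .iv_ramp import SweepSet
from .protocols import PerfusionProtocol
from .single_channel import PatchRecord

__all__ = [
    "write_sweeps_csv",
    "read_sweeps_csv",
    "write_patch_csv",
    "read_patch_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_protocol_json",
    "read_protocol_json",
    "write_sweeps_hdf5",
    "read_sweeps_hdf5",
]


def write_sweeps_csv(sweeps: SweepSet, path: str | Path) -> None:
    frames = []
    for s in range(sweeps.n_sweeps):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sweeps.time,
                    "voltage_mV": sweeps.voltage,
                    "sweep": s,
                    "current_pA": sweeps.current[s],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sweeps_csv(path: str | Path) -> SweepSet:
    df = pd.read_csv(path)
    required = {"time_s", "voltage_mV", "sweep", "current_pA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sweep CSV is missing columns: {sorted(missing)}")
    first = df[df["sweep"] == df["sweep"].min()]
    time = first["time_s"].to_numpy()
    voltage = first["voltage_mV"].to_numpy()
    current = np.vstack(
        [g["current_pA"].to_numpy() for _, g in df.groupby("sweep", sort=True)]
    )
    return SweepSet(time=time, voltage=voltage, current=current)


def write_patch_csv(records: list[PatchRecord], path: str | Path) -> None:
    frames = []
    for rec in records:
        t = np.arange(rec.current.size) / rec.sample_rate
        frames.append(pd.DataFrame({"time_s": t, "current_pA": rec.current, "Vp_mV": rec.vp}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_patch_csv(path: str | Path, v_rest: float = -60.0, sample_rate: float | None = None) -> list[PatchRecord]:
    df = pd.read_csv(path)
    required = {"time_s", "current_pA", "Vp_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patch CSV is missing columns: {sorted(missing)}")
    records = []
    for vp, g in df.groupby("Vp_mV", sort=True):
        t = g["time_s"].to_numpy()
        rate = sample_rate if sample_rate is not None else 1.0 / float(np.median(np.diff(t)))
        records.append(
            PatchRecord(current=g["current_pA"].to_numpy(), vp=float(vp), sample_rate=rate, v_rest=v_rest)
        )
    return records


def write_trace_csv(trace: FluoTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "F_au": trace.f}).to_csv(path, index=False)


def read_trace_csv(path: str | Path, protocol: PerfusionProtocol, cell_id: str = "", genotype: str = "") -> FluoTrace:
    df = pd.read_csv(path)
    required = {"time_s", "F_au"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    return FluoTrace(
        time=df["time_s"].to_numpy(), f=df["F_au"].to_numpy(), protocol=protocol, cell_id=cell_id, genotype=genotype
    )


def write_protocol_json(protocol: PerfusionProtocol, path: str | Path) -> None:
    Path(path).write_text(protocol.to_json())


def read_protocol_json(path: str | Path) -> PerfusionProtocol:
    return PerfusionProtocol.from_json(Path(path).read_text())


def write_params_json(params, path: str | Path) -> None:
    """Echo a pydantic parameter object as a JSON sidecar."""
    Path(path).write_text(params.model_dump_json(indent=2))


def write_sweeps_hdf5(sweeps: SweepSet, path: str | Path, params_json: str | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("sweeps")
        grp.create_dataset("time_s", data=sweeps.time)
        grp.create_dataset("voltage_mV", data=sweeps.voltage)
        grp.create_dataset("current_pA", data=sweeps.current)
        if params_json is not None:
            h5.create_group("params").attrs["json"] = params_json


def read_sweeps_hdf5(path: str | Path) -> SweepSet:
    import h5py

    with h5py.File(path, "r") as h5:
        grp = h5["sweeps"]
        return SweepSet(
            time=grp["time_s"][...], voltage=grp["voltage_mV"][...], current=grp["current_pA"][...]
        )
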