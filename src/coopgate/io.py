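"""Text and TIFF I/O for traces, sweeps, localization tables and stacks.

Traces are 2-column whitespace-delimited text (time_s, value) with a first
line of the form ``# {json metadata}`` carrying units, dt, preset name and
seed. Localization tables are delimited text with the header
``x_nm y_nm photons frame``. Image stacks are multi-page 16-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import LocalizationSet
from .traces import CalciumTrace, CurrentTrace, SweepSet

__all__ = [
    "write_trace",
    "read_trace",
    "write_sweeps",
    "read_sweeps",
    "write_localizations",
    "read_localizations",
    "write_stack",
    "read_stack",
    "write_json",
]


def _write_header(fh, meta: dict) -> None:
    fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")


def _read_header(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        try:
            return json.loads(first.lstrip("# ").strip())
        except json.JSONDecodeError:
            return {}
    return {}


def write_trace(path, trace: CalciumTrace | CurrentTrace, units: str = "", **meta) -> None:
    path = Path(path)
    header = {"dt_s": trace.dt, "units": units, **meta}
    with open(path, "w") as fh:
        _write_header(fh, header)
        for t, v in zip(trace.time, trace.values):
            fh.write(f"{t:.9g}\t{v:.9g}\n")


def read_trace(path, kind: str = "calcium"):
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    dt = float(meta.get("dt_s", data[1, 0] - data[0, 0] if data.shape[0] > 1 else 1.0))
    cls = CalciumTrace if kind == "calcium" else CurrentTrace
    trace = cls(values=data[:, 1], dt=dt)
    return trace, meta


def write_sweeps(path, sweeps: SweepSet, **meta) -> None:
    """Delimited text: time column plus one column per sweep."""
    path = Path(path)
    header = {"dt_s": sweeps.dt, "voltage_mV": sweeps.voltage, "n_sweeps": sweeps.n_sweeps, **meta}
    t = np.arange(sweeps.n_frames) * sweeps.dt
    table = np.column_stack([t, sweeps.sweeps.T])
    with open(path, "w") as fh:
        _write_header(fh, header)
        cols = "time_s\t" + "\t".join(f"sweep{i}" for i in range(sweeps.n_sweeps))
        fh.write(cols + "\n")
        np.savetxt(fh, table, fmt="%.9g", delimiter="\t")


def read_sweeps(path) -> tuple[SweepSet, dict]:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    dt = float(meta.get("dt_s", df.iloc[1, 0] - df.iloc[0, 0]))
    sweeps = df.iloc[:, 1:].to_numpy().T
    return SweepSet(sweeps=sweeps, dt=dt, voltage=float(meta.get("voltage_mV", np.nan))), meta


def write_localizations(path, locs: LocalizationSet, **meta) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            _write_header(fh, meta)
        fh.write("x_nm\ty_nm\tphotons\tframe\n")
        for x, y, p, f in zip(locs.x, locs.y, locs.photons, locs.frame):
            fh.write(f"{x:.3f}\t{y:.3f}\t{p:.1f}\t{int(f)}\n")


def read_localizations(path) -> LocalizationSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    return LocalizationSet(
        x=df["x_nm"].to_numpy(float),
        y=df["y_nm"].to_numpy(float),
        photons=df["photons"].to_numpy(float),
        frame=df["frame"].to_numpy(int),
    )


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, h, w) stack as multi-page 16-bit TIFF."""
    arr = np.asarray(stack)
    arr = np.round(np.clip(arr, 0, 65535)).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_json(path, obj) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, default=default)
        fh.write("\n")
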