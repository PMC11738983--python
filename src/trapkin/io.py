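"""Reading and writing traces and assay tables.

Trace CSV dialect: leading ``#``-comment header lines of the form
``# key: value`` (``fs_hz`` is mandatory; concentration and temperature
metadata optional), followed by columns ``time_s,transmission_V`` and an
optional ``true_state`` column on synthetic traces.  An HDF5 dialect is
provided for long recordings.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .ensemble_assays import CPMGPair, FPCurve, MeltCurve
from .signal_processing import TrapTrace

__all__ = [
    "read_trace", "write_trace",
    "read_fp_curve", "read_melt_curve", "read_cpmg_pair",
]

_META_KEYS = ("P_total_uM", "L_total_uM", "temperature_K", "seed", "label")


def _infer_dialect(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    return "hdf5" if suffix in (".h5", ".hdf5") else "csv"


def write_trace(trace: TrapTrace, path: Union[str, Path],
                dialect: Optional[str] = None) -> None:
    """Write a trace in the CSV (default) or HDF5 dialect."""
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        _write_trace_hdf5(trace, path)
        return
    if dialect != "csv":
        raise DataFormatError(f"unknown trace dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"# fs_hz: {trace.fs!r}\n")
        fh.write(f"# t0_s: {trace.t0!r}\n")
        for key in _META_KEYS:
            if key in trace.metadata:
                fh.write(f"# {key}: {trace.metadata[key]}\n")
        cols = {"time_s": trace.time(), "transmission_V": trace.values}
        if trace.true_state is not None:
            cols["true_state"] = trace.true_state.astype(int)
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_trace(path: Union[str, Path], dialect: Optional[str] = None) -> TrapTrace:
    """Read a trace, validating the header and time axis."""
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        return _read_trace_hdf5(path)
    if dialect != "csv":
        raise DataFormatError(f"unknown trace dialect {dialect!r}")

    header: dict = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    header[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if "fs_hz" not in header:
        raise DataFormatError(
            f"{path}: missing required '# fs_hz:' header line"
        )
    try:
        fs = float(header["fs_hz"])
    except ValueError as exc:
        raise DataFormatError(f"{path}: fs_hz is not numeric") from exc

    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    if "time_s" not in df.columns or "transmission_V" not in df.columns:
        raise DataFormatError(
            f"{path}: expected columns time_s,transmission_V; got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy()
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataFormatError(f"{path}: time column is not strictly increasing")

    metadata = {}
    for key in ("P_total_uM", "L_total_uM", "temperature_K"):
        if key in header:
            metadata[key] = float(header[key])
    if "seed" in header:
        metadata["seed"] = int(float(header["seed"]))
    if "label" in header:
        metadata["label"] = header["label"]

    true_state = (
        df["true_state"].to_numpy().astype(np.int8)
        if "true_state" in df.columns else None
    )
    return TrapTrace(
        values=df["transmission_V"].to_numpy(),
        fs=fs,
        t0=float(header.get("t0_s", t[0] if t.size else 0.0)),
        metadata=metadata,
        true_state=true_state,
    )


def _write_trace_hdf5(trace: TrapTrace, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("transmission_V", data=trace.values)
        if trace.true_state is not None:
            fh.create_dataset("true_state", data=trace.true_state)
        fh.attrs["fs_hz"] = trace.fs
        fh.attrs["t0_s"] = trace.t0
        for key in _META_KEYS:
            if key in trace.metadata:
                fh.attrs[key] = trace.metadata[key]


def _read_trace_hdf5(path) -> TrapTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        if "fs_hz" not in fh.attrs:
            raise DataFormatError(f"{path}: missing fs_hz attribute")
        values = fh["transmission_V"][:]
        true_state = fh["true_state"][:] if "true_state" in fh else None
        metadata = {k: fh.attrs[k] for k in _META_KEYS if k in fh.attrs}
        if "label" in metadata:
            metadata["label"] = str(metadata["label"])
        return TrapTrace(
            values=values,
            fs=float(fh.attrs["fs_hz"]),
            t0=float(fh.attrs.get("t0_s", 0.0)),
            metadata=metadata,
            true_state=true_state,
        )


def read_fp_curve(path: Union[str, Path]) -> FPCurve:
    """Read an FP titration table: ``conc_uM`` plus either ``P_mP`` or the
    two channel intensities ``I_par``/``I_perp``."""
    df = pd.read_csv(path, comment="#")
    if "conc_uM" not in df.columns:
        raise DataFormatError(f"{path}: missing 'conc_uM' column")
    if "P_mP" in df.columns:
        return FPCurve(concentrations_uM=df["conc_uM"].to_numpy(),
                       P_mP=df["P_mP"].to_numpy())
    if {"I_par", "I_perp"}.issubset(df.columns):
        return FPCurve(
            concentrations_uM=df["conc_uM"].to_numpy(),
            I_parallel=df["I_par"].to_numpy(),
            I_perpendicular=df["I_perp"].to_numpy(),
        )
    raise DataFormatError(
        f"{path}: need either P_mP or I_par,I_perp columns"
    )


def read_melt_curve(path: Union[str, Path]) -> MeltCurve:
    """Read a melt-curve table: ``temp_C`` plus ``I330``/``I350`` or ``ratio``."""
    df = pd.read_csv(path, comment="#")
    if "temp_C" not in df.columns:
        raise DataFormatError(f"{path}: missing 'temp_C' column")
    if {"I330", "I350"}.issubset(df.columns):
        return MeltCurve(temperature_C=df["temp_C"].to_numpy(),
                         I330=df["I330"].to_numpy(),
                         I350=df["I350"].to_numpy())
    if "ratio" in df.columns:
        return MeltCurve(temperature_C=df["temp_C"].to_numpy(),
                         ratio=df["ratio"].to_numpy())
    raise DataFormatError(f"{path}: need I330,I350 or ratio columns")


def read_cpmg_pair(path: Union[str, Path]) -> CPMGPair:
    """Read a one-row CPMG table: ``I_short,I_long,t_short_s,t_long_s``."""
    df = pd.read_csv(path, comment="#")
    required = {"I_short", "I_long", "t_short_s", "t_long_s"}
    if not required.issubset(df.columns):
        raise DataFormatError(f"{path}: need columns {sorted(required)}")
    row = df.iloc[0]
    return CPMGPair(
        I_short=float(row["I_short"]), I_long=float(row["I_long"]),
        t_short_s=float(row["t_short_s"]), t_long_s=float(row["t_long_s"]),
    )
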