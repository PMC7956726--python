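"""Signal I/O: CSV (time_s, amplitude_mV) and optional WFDB records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Signal

__all__ = ["read_signal", "write_signal", "read_wfdb", "write_sidecar"]

_CSV_COLUMNS = ("time_s", "amplitude_mV")


def read_signal(path, fmt: str | None = None) -> Signal:
    """Read a single-channel signal.

    CSV files carry two columns (time in seconds, amplitude in mV), with or
    without a header; the sampling rate is recovered from the median time
    step.  Other extensions must be read explicitly (see :func:`read_wfdb`).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt != "csv":
        raise ValueError(
            f"unknown format {fmt!r} for {path.name}; supported: csv "
            "(WFDB records via read_wfdb, optional extra)"
        )
    first = pd.read_csv(path, nrows=1, header=None)
    try:
        float(first.iloc[0, 0])
        df = pd.read_csv(path, header=None, names=_CSV_COLUMNS,
                         float_precision="round_trip")
    except (TypeError, ValueError):
        df = pd.read_csv(path, float_precision="round_trip")
        df.columns = _CSV_COLUMNS[: len(df.columns)]
    t = df[_CSV_COLUMNS[0]].to_numpy(dtype=float)
    y = df[_CSV_COLUMNS[1]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # 1-based data line of the offender
        raise ValueError(f"{path.name}: time column not strictly increasing "
                         f"near line {bad}")
    fs = 1.0 / float(np.median(dt))
    return Signal(y, fs=fs, t0=float(t[0]))


def write_signal(signal: Signal, path, header: bool = True) -> None:
    """Write a signal as full-precision CSV; round-trips losslessly."""
    df = pd.DataFrame({_CSV_COLUMNS[0]: signal.times,
                       _CSV_COLUMNS[1]: signal.samples})
    df.to_csv(path, index=False, header=header, float_format="%.17g")


def read_wfdb(record: str, channel: int = 0) -> Signal:
    """Read a WFDB record (optional dependency), in physical mV units."""
    try:
        import wfdb
    except ImportError as exc:
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install gaussecg[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(record, channels=[channel], physical=True)
    return Signal(np.asarray(rec.p_signal[:, 0], dtype=float), fs=float(rec.fs))


def write_sidecar(artifact_path, config: dict) -> None:
    """Write the JSON sidecar (full config + seed + version) for an artifact."""
    from . import __version__

    side = dict(config)
    side["gaussecg_version"] = __version__
    with open(str(artifact_path) + ".meta.json", "w") as fh:
        json.dump(side, fh, indent=1, default=str)
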