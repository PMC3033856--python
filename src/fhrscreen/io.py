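"""Plain-text file round-tripping for traces, manifests and reports.

Trace format: delimited text with columns ``time_s,fhr_bpm`` (header
optional).  When timestamps are absent or not strictly increasing, 4 Hz
sampling is assumed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_FS, Signal
from .errors import InvalidInputError


def read_trace(path, default_fs: float = DEFAULT_FS) -> Signal:
    """Load a two-column (time_s, fhr_bpm) delimited-text trace."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise InvalidInputError(f"cannot parse trace file {path}: {exc}") from exc
    if df.empty:
        raise InvalidInputError(f"trace file {path} holds no samples")
    # Headerless files come back with data in the column names.
    if "fhr_bpm" not in df.columns:
        try:
            df = pd.read_csv(path, comment="#", header=None,
                             float_precision="round_trip",
                             names=["time_s", "fhr_bpm"][: df.shape[1]])
        except Exception as exc:
            raise InvalidInputError(f"cannot parse trace file {path}: {exc}") from exc
    if "fhr_bpm" not in df.columns:
        if df.shape[1] == 1:
            df.columns = ["fhr_bpm"]
        else:
            raise InvalidInputError(f"trace file {path} needs an fhr_bpm column")
    values = pd.to_numeric(df["fhr_bpm"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).all():
        raise InvalidInputError(f"trace file {path} holds no numeric samples")
    fs = default_fs
    if "time_s" in df.columns:
        tt = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
        dt = np.diff(tt)
        if tt.size > 1 and np.all(np.isfinite(dt)) and np.all(dt > 0):
            step = float(np.median(dt))
            if step > 0:
                fs = 1.0 / step
    values = np.nan_to_num(values, nan=0.0)  # unparsable samples -> missing
    return Signal(values, sampling_rate=fs, id=path.stem)


def write_trace(trace: Signal, path, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        w = csv.writer(fh)
        w.writerow(["time_s", "fhr_bpm"])
        for t, v in zip(trace.times, trace.values):
            w.writerow([f"{t:.2f}", repr(float(v))])


def write_manifest(rows, path) -> None:
    """Dataset manifest: one row per trace (id, file, label, seed)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("trace_id", "file", "label"):
        if col not in df.columns:
            raise InvalidInputError(f"manifest lacks a '{col}' column")
    return df


def write_key_values(mapping: dict, path, header_comment: str = "") -> None:
    """Key-value structured text, one ``key = value`` pair per line."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for k, v in mapping.items():
            fh.write(f"{k} = {v}\n")


def read_key_values(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            out[k.strip()] = _parse_scalar(v.strip())
    return out


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    return s
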