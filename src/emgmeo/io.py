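"""CSV/JSON input-output for signals, events and metrics.

Formats (comma-separated, UTF-8, header required):

* signal CSV — columns ``time_s, emg``; timestamps must be uniform to within
  half a sample period.  A single ``emg`` column is accepted when the
  sampling rate is supplied explicitly.
* events CSV — columns ``event`` (onset/offset), ``time_s`` and optionally
  ``sample``; alternation is validated on read, writes are sorted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .evaluation import MetricsReport
from .signal import ChangePoint, ChangePointSet, Signal

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file."""


def read_signal(path: PathLike, fs: Optional[float] = None) -> Signal:
    """Read a signal CSV; infer the sampling rate from timestamps unless given."""
    df = pd.read_csv(path)
    if "emg" not in df.columns:
        raise FormatError(f"{path}: missing required column 'emg' (found {list(df.columns)})")
    samples = df["emg"].to_numpy(dtype=np.float64)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=np.float64)
        dt = np.diff(t)
        if dt.size == 0:
            raise FormatError(f"{path}: need at least 2 rows to infer sampling")
        period = np.median(dt)
        if period <= 0:
            bad = int(np.argmax(dt <= 0)) + 2  # +2: header + 1-based
            raise FormatError(f"{path}: non-increasing timestamps near line {bad}")
        jitter = np.abs(dt - period)
        if jitter.max() >= 0.5 * period:
            bad = int(np.argmax(jitter >= 0.5 * period)) + 2
            raise FormatError(
                f"{path}: non-uniform sampling near line {bad} "
                f"(jitter {jitter.max():.3g} s vs period {period:.3g} s)"
            )
        inferred = 1.0 / period
        fs = fs if fs is not None else inferred
    elif fs is None:
        raise FormatError(f"{path}: no 'time_s' column and no sampling rate given")
    return Signal(samples, fs)


def write_signal(signal: Signal, path: PathLike) -> None:
    pd.DataFrame({"time_s": np.round(signal.times, 6), "emg": signal.samples}).to_csv(
        path, index=False
    )


def read_events(path: PathLike, fs: float) -> ChangePointSet:
    """Read an events CSV and validate alternation."""
    df = pd.read_csv(path)
    for col in ("event", "time_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events = []
    for _, row in df.iterrows():
        kind = str(row["event"]).strip().lower()
        t = float(row["time_s"])
        idx = int(row["sample"]) if "sample" in df.columns else int(round(t * fs))
        events.append(ChangePoint(kind, t, idx))
    try:
        return ChangePointSet(tuple(events))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_events(events: ChangePointSet, path: PathLike) -> None:
    df = events.to_frame()
    df["time_s"] = df["time_s"].round(6)
    df.to_csv(path, index=False)


def write_metrics(report: MetricsReport, path: PathLike, extra: Optional[dict] = None) -> None:
    payload = dict(extra or {})
    payload.update(report.as_dict())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
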