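"""Reading and writing perfusion traces.

The on-disk format is a small CSV with columns ``time_s``,
``perfusion_ml_100g_min`` and ``phase`` plus ``# key=value`` header
comments carrying the protocol and free-form metadata, so a write→read
round trip is lossless.  A best-effort adapter for MATLAB-container
perfusion files is also provided.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .simulator import CuffProtocol, PerfusionTrace

__all__ = ["TraceParseError", "read_trace", "write_trace", "load_matlab_traces"]

REQUIRED_COLUMNS = ("time_s", "perfusion_ml_100g_min")

_PROTOCOL_KEYS = ("t_baseline", "t_cuff", "t_recovery", "dt_sample")


class TraceParseError(ValueError):
    """Raised when a trace file is malformed."""


def write_trace(trace: PerfusionTrace, path: str | Path) -> None:
    """Write a trace as annotated CSV."""
    p = trace.protocol
    lines = ["# aslrh-trace v1"]
    for key in _PROTOCOL_KEYS:
        lines.append(f"# {key}={getattr(p, key)!r}")
    for key, val in trace.meta.items():
        lines.append(f"# meta.{key}={val!r}")
    frame = pd.DataFrame(
        {
            "time_s": trace.t,
            "perfusion_ml_100g_min": trace.f,
            "phase": p.phase_of(trace.t),
        }
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_trace(path: str | Path) -> PerfusionTrace:
    """Read a trace written by :func:`write_trace`.

    Raises :class:`TraceParseError` naming the offending column or row
    when the file is malformed.
    """
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(text):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" in line:
            key, _, val = line[1:].partition("=")
            header[key.strip()] = val.strip()
    try:
        frame = pd.read_csv(_io.StringIO("\n".join(text[body_start:])))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TraceParseError(f"{path}: unreadable CSV body: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise TraceParseError(f"{path}: missing required column {col!r}")
    bad = frame[REQUIRED_COLUMNS[1]].isna()
    if bad.any():
        raise TraceParseError(
            f"{path}: non-numeric perfusion at row {int(np.argmax(bad.values)) + 1}"
        )
    proto_kwargs = {}
    for key in _PROTOCOL_KEYS:
        if key in header:
            try:
                proto_kwargs[key] = float(header[key])
            except ValueError as exc:
                raise TraceParseError(f"{path}: bad protocol value for {key}") from exc
    protocol = CuffProtocol(**proto_kwargs) if proto_kwargs else CuffProtocol()
    meta = {
        key[len("meta."):]: _unquote(val)
        for key, val in header.items()
        if key.startswith("meta.")
    }
    try:
        return PerfusionTrace(
            t=frame["time_s"].to_numpy(float),
            f=frame["perfusion_ml_100g_min"].to_numpy(float),
            protocol=protocol,
            meta=meta,
        )
    except ValueError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc


def _unquote(val: str):
    if len(val) >= 2 and val[0] == val[-1] == "'":
        return val[1:-1]
    try:
        return float(val)
    except ValueError:
        return val


def load_matlab_traces(
    path: str | Path,
    protocol: CuffProtocol | None = None,
) -> list[PerfusionTrace]:
    """Best-effort reader for MATLAB-container perfusion data.

    Scans the file for numeric arrays that look like perfusion–time
    recordings: a 2×N or N×2 array is taken as (time, perfusion); a 1-D
    array of length ≥ 10 is taken as perfusion sampled at the default
    repetition time.  Returns one trace per recognised array; the caller
    supplies the protocol (2-min cuff by default).
    """
    protocol = protocol or CuffProtocol()
    mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    traces: list[PerfusionTrace] = []
    for name, val in mat.items():
        if name.startswith("__"):
            continue
        arr = np.asarray(val, dtype=object)
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError):
            continue
        if arr.ndim == 2 and 2 in arr.shape and arr.size >= 20:
            pair = arr if arr.shape[0] == 2 else arr.T
            order = np.argsort(pair[0])
            traces.append(
                PerfusionTrace(pair[0, order], pair[1, order], protocol, {"name": name})
            )
        elif arr.ndim == 1 and arr.size >= 10:
            t = protocol.sample_times(include_cuff=False)[: arr.size]
            if t.size == arr.size:
                traces.append(PerfusionTrace(t, arr, protocol, {"name": name}))
    return traces
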