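"""Time-series container and delimited-text I/O.

All traces in this package are plain ``(time, value)`` series.  Time is in
seconds with ``t = 0`` anchored, by convention, at the offset of the last
stimulus pulse; values are either membrane capacitance (pF) or normalized
fluorescence (dimensionless).  Provenance (scenario name, seed, stimulus
times) travels in ``meta`` so downstream fits can validate their inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_trace", "write_trace"]


@dataclass
class TimeSeries:
    """A uniformly or irregularly sampled trace.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing, length >= 2.
    v : array of float
        Sample values, same length as ``t``.
    units : str
        Unit label for ``v`` (e.g. ``"pF"``, ``"norm"``).
    meta : dict
        Free-form provenance (scenario name, seed, pulse times, notes).
    """

    t: np.ndarray
    v: np.ndarray
    units: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if not self.units:
            raise ValueError("units label must be non-empty")

    def __len__(self) -> int:
        return self.t.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def crop(self, t_min: float = -np.inf, t_max: float = np.inf) -> "TimeSeries":
        mask = (self.t >= t_min) & (self.t <= t_max)
        if mask.sum() < 2:
            raise ValueError(f"crop [{t_min}, {t_max}] leaves fewer than 2 samples")
        return TimeSeries(self.t[mask], self.v[mask], self.units, dict(self.meta))

    def interp(self, t_s: float | np.ndarray) -> float | np.ndarray:
        """Nearest-two linear interpolation; errors outside the span."""
        t_s = np.asarray(t_s, dtype=float)
        if np.any(t_s < self.t[0]) or np.any(t_s > self.t[-1]):
            raise ValueError(f"time {t_s} outside trace span {self.span}")
        out = np.interp(t_s, self.t, self.v)
        return float(out) if out.ndim == 0 else out

    def copy_with(self, v: np.ndarray | None = None, **meta: Any) -> "TimeSeries":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return TimeSeries(self.t.copy(), self.v.copy() if v is None else np.asarray(v, float), self.units, new_meta)


def _meta_to_json(meta: dict[str, Any]) -> str:
    def default(o: Any) -> Any:
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    return json.dumps(meta, default=default)


def write_trace(ts: TimeSeries, path: str | Path) -> None:
    """Write a trace as CSV with header ``time_s,value,units``.

    Values are written with 12 significant digits so a write/read round trip
    is lossless at that precision; ``meta`` is stored as a JSON comment line.
    """
    path = Path(path)
    with path.open("w") as fh:
        if ts.meta:
            fh.write("# meta=" + _meta_to_json(ts.meta) + "\n")
        fh.write("time_s,value,units\n")
        for t, v in zip(ts.t, ts.v):
            fh.write(f"{t:.12g},{v:.12g},{ts.units}\n")


def read_trace(path: str | Path) -> TimeSeries:
    """Read a CSV trace written by :func:`write_trace`.

    Raises
    ------
    ValueError
        On a malformed header or non-monotone time column, naming the
        offending line.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    with path.open() as fh:
        first = fh.readline()
        header_line = 1
        if first.startswith("# meta="):
            meta = json.loads(first[len("# meta="):])
            first = fh.readline()
            header_line = 2
        cols = [c.strip() for c in first.strip().split(",")]
        if cols != ["time_s", "value", "units"]:
            raise ValueError(
                f"{path}:{header_line}: expected header 'time_s,value,units', got {first.strip()!r}"
            )
        df = pd.read_csv(fh, names=["time_s", "value", "units"])
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        line = header_line + 1 + int(bad[0]) + 1
        raise ValueError(f"{path}:{line}: time not strictly increasing")
    units = str(df["units"].iloc[0])
    return TimeSeries(t, df["value"].to_numpy(dtype=float), units, meta)
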