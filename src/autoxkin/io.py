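"""Plain-text file formats for traces, ledgers, metrics and run configs.

Traces are comma-delimited text with ``#``-prefixed metadata headers::

    # autoxkin_version: 0.1.0
    # time_unit: s
    # o2_unit: M
    # injection_time_s: 183.2
    # medium: micelle
    ...
    time_s,o2_consumed_M
    0,0
    5,2.7418e-06

Files are tiny (<= 1e4 points) and human-diffable; round trips preserve
values to full double precision.  A legacy ``time_unit: min`` header is
converted to seconds on read.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AutoxkinWarning, TraceFormatError
from .trace import Trace

__all__ = ["read_trace", "write_trace", "write_metrics", "write_ledger",
           "RunConfig", "load_config", "config_hash"]

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "seconds": 1.0,
                 "min": 60.0, "minutes": 60.0}


def _fmt(value: float) -> str:
    return format(value, ".17g")


def write_trace(trace: Trace, path) -> None:
    """Write a trace as delimited text with ``#`` metadata headers."""
    path = Path(path)
    lines = [f"# autoxkin_version: {__version__}",
             "# time_unit: s",
             "# o2_unit: M",
             f"# injection_time_s: {_fmt(trace.injection_time)}"]
    for key, value in trace.metadata.items():
        if key in ("time_unit", "o2_unit", "injection_time_s"):
            continue
        lines.append(f"# {key}: {value}")
    lines.append("time_s,o2_consumed_M")
    for t, y in zip(trace.times, trace.o2_consumed):
        lines.append(f"{_fmt(t)},{_fmt(y)}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    """Read a trace file, validating the format contract.

    Raises :class:`TraceFormatError` (naming the first offending row) for
    a non-monotonic time column; warns and assumes injection at t = 0 when
    the header lacks ``injection_time_s``.
    """
    path = Path(path)
    metadata: dict = {}
    times, o2, linenos = [], [], []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            metadata[key.strip()] = value.strip()
            continue
        if not header_seen:
            header_seen = True          # column-name row
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise TraceFormatError(
                f"{path.name}: row {lineno}: expected 2 columns, "
                f"got {len(parts)}")
        try:
            times.append(float(parts[0]))
            o2.append(float(parts[1]))
        except ValueError as exc:
            raise TraceFormatError(
                f"{path.name}: row {lineno}: {exc}") from None
        linenos.append(lineno)

    unit = metadata.pop("time_unit", "s").lower()
    if unit not in _TIME_FACTORS:
        raise TraceFormatError(f"{path.name}: unknown time_unit {unit!r}")
    factor = _TIME_FACTORS[unit]
    t = np.asarray(times) * factor
    y = np.asarray(o2)

    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TraceFormatError(
            f"{path.name}: time column not strictly increasing at "
            f"row {linenos[bad[0] + 1]} "
            f"(t = {t[bad[0] + 1] / factor:g} {unit})")

    if "injection_time_s" in metadata:
        t_inj = float(metadata.pop("injection_time_s"))
        if unit != "s":                 # legacy files store it in their unit
            t_inj *= 1.0
    elif "injection_time" in metadata:
        t_inj = float(metadata.pop("injection_time")) * factor
    else:
        warnings.warn(
            f"{path.name}: no injection_time in header; induction times "
            "will be measured from t = 0", AutoxkinWarning, stacklevel=2)
        t_inj = 0.0
    metadata.pop("o2_unit", None)
    return Trace(times=t, o2_consumed=y, injection_time=t_inj,
                 metadata=metadata)


def write_metrics(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a metrics (or synergy/truth) table with ``#`` headers."""
    path = Path(path)
    lines = [f"# autoxkin_version: {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    csv = df.to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + csv)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ledger(species: pd.DataFrame, path,
                 metadata: dict | None = None) -> None:
    """Export a species ledger: one column per species, '#' metadata."""
    path = Path(path)
    lines = [f"# autoxkin_version: {__version__}",
             "# time_unit: s", "# conc_unit: M"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    csv = species.reset_index().to_csv(index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + csv)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one CLI run (flat key-value blocks, YAML on disk)."""

    traces: list[str] = field(default_factory=list)
    system: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        for p in self.traces:
            if not Path(p).exists():
                raise FileNotFoundError(f"trace file not found: {p}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(obj) -> str:
    """Short stable hash of a config-like mapping, for output provenance."""
    if isinstance(obj, RunConfig):
        obj = obj.__dict__
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
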