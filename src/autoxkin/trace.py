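"""The oxygen-uptake trace container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trace:
    """A cumulative oxygen-uptake time series.

    Attributes
    ----------
    times : ndarray
        Seconds from initiator start, strictly increasing.
    o2_consumed : ndarray
        Cumulative molar O2 uptake; starts at 0 and is non-decreasing for
        noiseless traces.
    injection_time : float
        Seconds at which the antioxidant was added (0 if present from the
        start).  Induction times are reported relative to this instant.
    metadata : dict
        System description and generator provenance (medium, pH label,
        compound roster, seed, noise sigma, ...).
    """

    times: np.ndarray
    o2_consumed: np.ndarray
    injection_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.o2_consumed = np.asarray(self.o2_consumed, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.o2_consumed.shape:
            raise ValueError("times and o2_consumed must be 1-D and equal length")
        if self.times.size >= 2:
            bad = np.nonzero(np.diff(self.times) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"times must be strictly increasing; first violation at "
                    f"row {bad[0] + 1} (t={self.times[bad[0] + 1]:g})")

    def __len__(self) -> int:
        return self.times.size

    def post_injection(self) -> tuple[np.ndarray, np.ndarray]:
        """Times (relative to injection) and uptake (re-zeroed at injection)
        for the part of the record after antioxidant addition."""
        mask = self.times >= self.injection_time
        t = self.times[mask] - self.injection_time
        y = self.o2_consumed[mask]
        if t.size == 0:
            return t, y
        y0 = np.interp(self.injection_time, self.times, self.o2_consumed)
        return t, y - y0

    def compounds(self) -> dict[str, float]:
        """Antioxidant roster recorded in the metadata, name -> conc (M)."""
        raw = self.metadata.get("compounds", "")
        out: dict[str, float] = {}
        if isinstance(raw, dict):
            return {str(k): float(v) for k, v in raw.items()}
        for item in str(raw).split(","):
            item = item.strip()
            if not item:
                continue
            name, _, conc = item.partition(":")
            out[name.strip()] = float(conc)
        return out
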