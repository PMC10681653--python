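"""Uniformly sampled timeseries and event containers.

These are the two in-memory currencies of the pipeline: ``SampledSeries``
holds anything on a regular time grid (raw sensor traces, frame-aligned
HBI/RVT, network BOLD averages) and ``EventSeries`` holds point events
(systolic peaks, breath extrema) with optional amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DegenerateSignalError(ValueError):
    """Raised when an operation receives a constant or empty signal."""


@dataclass
class SampledSeries:
    """A real-valued series sampled at uniform step ``dt`` starting at ``t0``."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def with_values(self, values: np.ndarray, label: str | None = None) -> "SampledSeries":
        return replace(self, values=np.asarray(values, float),
                       label=self.label if label is None else label)


@dataclass
class EventSeries:
    """Point events in time: pulse peaks or breath extrema."""

    times: np.ndarray
    amplitudes: np.ndarray | None = None
    kind: str = "pulse-peak"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.shape != self.times.shape:
                raise ValueError("amplitudes must match times")
            if not np.all(np.isfinite(self.amplitudes)):
                raise ValueError("amplitudes must be finite")

    def __len__(self) -> int:
        return self.times.size
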