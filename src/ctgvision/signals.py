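"""Uniformly sampled physical-unit time series shared across the package.

A cardiotocograph (CTG) pairs a fetal heart rate (FHR) trace in beats per
minute with a uterine contraction (UC) pressure trace in mmHg.  Both are
represented here as :class:`TraceSignal`: a uniformly sampled value array, a
per-sample validity mask (columns where no trace pixel was found stay
interpolated but flagged), the sample rate and the start time of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Chart axis span for the fetal heart rate channel, beats per minute.
FHR_RANGE = (60.0, 210.0)
#: Chart axis span for the uterine contraction channel, mmHg.
UC_RANGE = (0.0, 100.0)

CHANNEL_RANGES = {"fhr": FHR_RANGE, "uc": UC_RANGE}


@dataclass
class TraceSignal:
    """A uniformly sampled FHR or UC series with a validity mask."""

    values: np.ndarray
    sample_rate: float
    channel: str  # "fhr" or "uc"
    valid: np.ndarray = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel not in CHANNEL_RANGES:
            raise ValueError(f"unknown channel {self.channel!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (left-aligned to start_time)."""
        return self.start_time + np.arange(len(self.values)) / self.sample_rate

    @property
    def value_range(self) -> tuple[float, float]:
        return CHANNEL_RANGES[self.channel]

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the series at arbitrary times (edge-held)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)
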