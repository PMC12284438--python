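"""Periodic sampled waveforms (flow in mL/s, pressure in mmHg)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Waveform"]


@dataclass(frozen=True)
class Waveform:
    """One period of a uniformly sampled periodic signal.

    ``time`` holds N strictly increasing samples starting at 0 with spacing
    ``period / N`` (the sample at t = period is the same as t = 0 and is not
    stored).  ``values`` are flow (mL/s) or pressure (mmHg).
    """

    time: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("waveform needs at least 2 time samples")
        if v.shape != t.shape:
            raise ValueError("time and values must have the same length")
        if not self.period > 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        dt = self.period / t.size
        if abs(t[0]) > 1e-12 * self.period or np.max(np.abs(np.diff(t) - dt)) > 1e-9 * dt:
            raise ValueError("waveform must be uniformly sampled over exactly one period, starting at 0")

    @property
    def dt(self) -> float:
        return self.period / self.time.size

    @property
    def n(self) -> int:
        return self.time.size

    def mean(self) -> float:
        return float(np.mean(self.values))

    def cycle_volume(self) -> float:
        """Integral over one period (for a flow waveform: stroke volume, mL)."""
        return float(np.sum(self.values) * self.dt)

    def interp(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        t = np.asarray(t, dtype=float)
        tm = np.mod(t, self.period)
        idx = tm / self.dt
        i0 = np.floor(idx).astype(int) % self.n
        i1 = (i0 + 1) % self.n
        frac = idx - np.floor(idx)
        return (1.0 - frac) * self.values[i0] + frac * self.values[i1]

    def resample(self, n: int) -> "Waveform":
        t = np.arange(n) * (self.period / n)
        return Waveform(t, self.interp(t), self.period)

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.time, factor * self.values, self.period)

    def with_values(self, values) -> "Waveform":
        return Waveform(self.time, np.asarray(values, dtype=float), self.period)
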