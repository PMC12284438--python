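"""Pulmonary arterial impedance: Z(omega), Z0, Zc, and pulse indices.

One period of paired pressure/flow waveforms is Fourier-transformed and the
input impedance Z(omega) = P(omega)/Q(omega) evaluated at the cardiac
harmonics.  Z0 is the 0 Hz value (ratio of means); the characteristic
impedance Zc is the average of |Z| over harmonics in (0, f_max] Hz.  By the
pulse-pressure convention the diastolic baseline is removed from P before
transforming, which changes only Z0, never Zc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "ImpedanceSpectrum",
    "pulse_pressure_waveform",
    "impedance_spectrum",
    "z0",
    "zc",
    "delta_mpa_pressure",
]

#: harmonics with |Q(omega)| below this fraction of the first harmonic are
#: masked to avoid division blow-up
HARMONIC_FLOOR = 1.0e-6


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Impedance at the cardiac harmonics (mmHg.s/mL).

    ``frequencies`` start at 0 Hz and step by 1/T; ``masked`` marks
    harmonics with negligible flow content, excluded from Zc.
    """

    frequencies: np.ndarray
    z: np.ndarray
    masked: np.ndarray
    convention: str = "pulse"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f[0] != 0.0 or np.any(f < 0):
            raise ValueError("harmonic frequencies must start at 0 Hz and be non-negative")


def pulse_pressure_waveform(p: Waveform) -> Waveform:
    """Subtract the diastolic (minimum) pressure; the result's minimum is 0."""
    return p.with_values(p.values - np.min(p.values))


def delta_mpa_pressure(p: Waveform) -> float:
    """Pulse pressure: systolic minus diastolic (max - min), mmHg."""
    return float(np.max(p.values) - np.min(p.values))


def impedance_spectrum(p: Waveform, q: Waveform, convention: str = "pulse") -> ImpedanceSpectrum:
    """Z(omega) = P(omega)/Q(omega) at the harmonics of one period.

    Requires identical sampling of the two waveforms.  With the 'pulse'
    convention the diastolic baseline is subtracted from P first (affects
    only the 0 Hz value).  Harmonics whose flow magnitude falls below
    ``HARMONIC_FLOOR`` times the first harmonic's are masked and logged.
    """
    if convention not in ("pulse", "full"):
        raise ValueError(f"convention must be 'pulse' or 'full', got {convention!r}")
    if abs(p.period - q.period) > 1e-12 * q.period or p.n != q.n:
        raise ValueError("pressure and flow waveforms must share period and sampling")
    if convention == "pulse":
        p = pulse_pressure_waveform(p)
    n = p.n
    p_hat = np.fft.rfft(p.values) / n
    q_hat = np.fft.rfft(q.values) / n
    freqs = np.arange(p_hat.size) / p.period
    floor = HARMONIC_FLOOR * (np.abs(q_hat[1]) if q_hat.size > 1 else 0.0)
    masked = np.abs(q_hat) < floor
    n_masked = int(np.sum(masked[1:]))
    if n_masked:
        logger.info("masked %d low-flow harmonics in the impedance spectrum", n_masked)
    z = np.divide(p_hat, q_hat, out=np.full_like(p_hat, np.nan), where=~masked)
    return ImpedanceSpectrum(freqs, z, masked, convention)


def z0(spec: ImpedanceSpectrum) -> float:
    """Impedance at 0 Hz: the real ratio of mean pressure to mean flow."""
    if spec.masked[0]:
        raise ValueError("mean flow is (near) zero; Z0 undefined")
    return float(np.real(spec.z[0]))


def zc(spec: ImpedanceSpectrum, f_max: float = 250.0) -> float:
    """Characteristic impedance: mean of |Z| over harmonics in (0, f_max] Hz."""
    nyquist = spec.frequencies[-1]
    if nyquist < f_max:
        raise ValueError(
            f"waveform Nyquist frequency {nyquist:.1f} Hz is below f_max={f_max} Hz"
        )
    sel = (spec.frequencies > 0) & (spec.frequencies <= f_max) & ~spec.masked
    if np.sum(sel) < 3:
        raise ValueError(
            f"only {int(np.sum(sel))} usable harmonics in (0, {f_max}] Hz; "
            "sample a longer or finer waveform"
        )
    return float(np.mean(np.abs(spec.z[sel])))
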