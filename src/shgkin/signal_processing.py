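"""Inversion of the SHG instrument chain.

Measured photon counts are attenuated by sample extinction and sit on an
incoherent hyper-Rayleigh background from dye free in solution.  The
processing order is fixed by the measurement model: extinction correction
first, then background subtraction, then the square root that converts the
scattering intensity to the coherent SHG field.  Finally the decay origin
``t0`` is located as the smoothed field maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import SHGTrace

__all__ = [
    "FieldTrace",
    "CorrectionModel",
    "correct_intensity",
    "subtract_background",
    "to_field",
    "detect_peak",
    "process_trace",
]


@dataclass(frozen=True)
class FieldTrace:
    """Corrected, background-subtracted SHG field (square root of intensity)."""

    time: np.ndarray
    field: np.ndarray
    temperature: float
    meta: dict = field(default_factory=dict)
    t_peak: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.field, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if f.shape != t.shape or np.any(f < 0):
            raise ValueError("field must be nonnegative and match the time grid")
        if self.t_peak is not None and not t[0] <= self.t_peak <= t[-1]:
            raise ValueError("t_peak must lie within the time range")


@dataclass(frozen=True)
class CorrectionModel:
    """Extinction correction and hyper-Rayleigh background level.

    The scalar ``extinction_factor`` (>= 1) is the default mode.  It may
    instead be computed from an extinction spectrum via Beer-Lambert,
    combining the attenuation at the fundamental and the second harmonic:
    ``10**(A_fund * l_eff) * 10**(A_shg * l_eff)``.
    """

    extinction_factor: float = 1.0
    hrs_level: float = 0.0

    def __post_init__(self) -> None:
        if self.extinction_factor < 1.0:
            raise ValueError("extinction_factor must be >= 1")
        if self.hrs_level < 0:
            raise ValueError("hrs_level must be >= 0")

    @classmethod
    def from_spectrum(
        cls,
        wavelength_nm: np.ndarray,
        extinction: np.ndarray,
        path_length: float,
        hrs_level: float = 0.0,
        fundamental_nm: float = 810.0,
        shg_nm: float = 405.0,
    ) -> "CorrectionModel":
        """Beer-Lambert extinction factor from a measured spectrum.

        ``extinction`` is decadic absorbance per unit path; ``path_length``
        is the effective optical path in the same units.
        """
        wl = np.asarray(wavelength_nm, dtype=float)
        ext = np.asarray(extinction, dtype=float)
        if wl.shape != ext.shape or wl.ndim != 1:
            raise ValueError("wavelength and extinction must be 1-d, equal length")
        a_fund = np.interp(fundamental_nm, wl, ext)
        a_shg = np.interp(shg_nm, wl, ext)
        factor = float(10.0 ** (a_fund * path_length) * 10.0 ** (a_shg * path_length))
        return cls(extinction_factor=max(factor, 1.0), hrs_level=hrs_level)


def correct_intensity(trace: SHGTrace, model: CorrectionModel) -> np.ndarray:
    """Undo the sample extinction: ``I_corr = I_raw * extinction_factor``."""
    return np.asarray(trace.counts, dtype=float) * model.extinction_factor


def subtract_background(corrected: np.ndarray, hrs_level: float) -> np.ndarray:
    """Remove the hyper-Rayleigh floor, clamping Poisson undershoot at zero."""
    if hrs_level < 0:
        raise ValueError("hrs_level must be >= 0")
    corrected = np.asarray(corrected, dtype=float)
    if hrs_level > 0 and hrs_level >= corrected.max():
        warnings.warn(
            "hyper-Rayleigh level exceeds the trace maximum; the trace is "
            "likely vesicle-free",
            stacklevel=2,
        )
    return np.clip(corrected - hrs_level, 0.0, None)


def to_field(net_intensity: np.ndarray) -> np.ndarray:
    """SHG field: elementwise square root of the net scattering intensity."""
    net = np.asarray(net_intensity, dtype=float)
    if np.any(net < 0):
        raise ValueError("net intensity must be nonnegative")
    return np.sqrt(net)


def detect_peak(time: np.ndarray, fieldvals: np.ndarray, window: int = 5) -> float:
    """Decay origin: time of the moving-average-smoothed field maximum.

    Ties break to the earliest time.  A trace whose smoothed maximum sits on
    the final point has no decay phase and raises (incomplete acquisition).
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(fieldvals, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if f.size < 3 * window:
        raise ValueError(f"need at least {3 * window} points for window={window}")
    kernel = np.ones(window) / window
    # 'same' convolution; edge bins average over fewer points
    smooth = np.convolve(f, kernel, mode="same")
    norm = np.convolve(np.ones_like(f), kernel, mode="same")
    smooth = smooth / norm
    idx = int(np.argmax(smooth))  # argmax returns the first (earliest) maximum
    if idx >= f.size - 1:
        raise ValueError("field is still rising at the end of the trace; no decay phase")
    return float(t[idx])


def process_trace(
    trace: SHGTrace, model: CorrectionModel, peak_window: int = 5
) -> FieldTrace:
    """Full chain: extinction correction -> background subtraction -> sqrt -> peak."""
    net = subtract_background(correct_intensity(trace, model), model.hrs_level)
    f = to_field(net)
    t_peak = detect_peak(trace.time, f, window=peak_window)
    return FieldTrace(
        time=np.asarray(trace.time, dtype=float),
        field=f,
        temperature=trace.temperature,
        meta=dict(trace.meta),
        t_peak=t_peak,
    )
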