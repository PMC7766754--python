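"""Windowed-sinc low-pass filter: the classic post-processing baseline.

The square-wave ground-truth signal contains level transitions whose spectrum
extends far above the content of a real pore signal.  The traditional remedy
is a linear-phase FIR low-pass: a sinc kernel tapered by a Blackman window,
normalized to unit DC gain.  The default cutoff is 950 Hz at a 4 kHz sample
rate; the firwin convention places the half-amplitude point at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import ValidationError


@dataclass(frozen=True)
class FilterSpec:
    cutoff_hz: float = 950.0
    sample_rate_hz: float = 4000.0
    kernel_length: int = 129

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValidationError("cutoff_hz must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if self.cutoff_hz >= self.sample_rate_hz / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist frequency "
                f"{self.sample_rate_hz / 2} Hz"
            )
        if self.kernel_length < 3 or self.kernel_length % 2 == 0:
            raise ValidationError("kernel_length must be an odd integer >= 3")


DEFAULT_FILTER = FilterSpec()


def design_kernel(spec: FilterSpec = DEFAULT_FILTER) -> np.ndarray:
    """Blackman-windowed sinc kernel, symmetric, normalized to unit sum."""
    return sps.firwin(
        spec.kernel_length,
        spec.cutoff_hz,
        window="blackman",
        fs=spec.sample_rate_hz,
    )


def frequency_response(
    kernel: np.ndarray, sample_rate_hz: float, n_points: int = 16384
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude response |H(f)| of an FIR kernel on a dense frequency grid."""
    freqs, h = sps.freqz(kernel, worN=n_points, fs=sample_rate_hz)
    return freqs, np.abs(h)


def half_gain_frequency(spec: FilterSpec = DEFAULT_FILTER) -> float:
    """Frequency (Hz) at which the kernel's magnitude response crosses 0.5."""
    freqs, mag = frequency_response(design_kernel(spec), spec.sample_rate_hz)
    below = np.nonzero(mag < 0.5)[0]
    if len(below) == 0:
        raise ValidationError("magnitude response never drops below 0.5")
    i = below[0]
    # linear interpolation between the two grid points bracketing the crossing
    f0, f1 = freqs[i - 1], freqs[i]
    m0, m1 = mag[i - 1], mag[i]
    return float(f0 + (0.5 - m0) * (f1 - f0) / (m1 - m0))


def lowpass_filter(
    signal: Sequence[float] | np.ndarray, spec: FilterSpec = DEFAULT_FILTER
) -> np.ndarray:
    """Convolve with the windowed-sinc kernel; edges replicated, length kept."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 1:
        raise ValidationError("signal must be a non-empty 1-D array")
    kernel = design_kernel(spec)
    half = (spec.kernel_length - 1) // 2
    padded = np.pad(signal, half, mode="edge")
    return np.convolve(padded, kernel, mode="valid")
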