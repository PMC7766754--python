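"""Similarity metrics between simulated and real signals.

Two complementary views:

* time domain - normalized DTW distance: the minimum warp cost between the
  z-scored signals divided by the warp-path length, so reads of different
  lengths are comparable;
* frequency domain - continuous wavelet transform (Morlet) magnitude spectra
  compared by Pearson correlation, overall and split into low- and
  high-frequency bands at the base-translocation rate (450 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ValidationError
from .labeling import dtw_path
from .synthesis import zscore_normalize

# standard Morlet with angular center frequency w0 = 6; for the pywt complex
# Morlet family this is center frequency w0 / (2 pi) cycles with bandwidth 2
MORLET_W0 = 6.0
_WAVELET_NAME = f"cmor2.0-{MORLET_W0 / (2.0 * np.pi):.9f}"


@dataclass(frozen=True)
class CWTSpectrum:
    """Time-frequency magnitude matrix (scales x time), frequencies descending."""

    magnitudes: np.ndarray
    frequencies_hz: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float)
        freqs = np.asarray(self.frequencies_hz, dtype=float)
        object.__setattr__(self, "magnitudes", mags)
        object.__setattr__(self, "frequencies_hz", freqs)
        if mags.ndim != 2 or mags.shape[0] != len(freqs):
            raise ValidationError("magnitudes must be (n_scales, T) with one row per frequency")
        if np.any(mags < 0):
            raise ValidationError("magnitudes must be non-negative")
        if np.any(np.diff(freqs) >= 0):
            raise ValidationError("frequencies must be strictly descending")


def normalized_dtw(
    a,
    b,
    normalize: bool = True,
    band_radius: int | None = None,
) -> float:
    """DTW cost per warp-path step between (by default) z-scored signals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if normalize:
        a, _ = zscore_normalize(a)
        b, _ = zscore_normalize(b)
    path = dtw_path(a, b, band_radius=band_radius)
    return path.total_cost / len(path)


def cwt_spectrum(
    signal,
    n_scales: int = 64,
    sample_rate_hz: float = 4000.0,
) -> CWTSpectrum:
    """Morlet CWT magnitude spectrum on a log-spaced pseudo-frequency grid.

    Frequencies span [sample_rate / length, sample_rate / 2], descending.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 16:
        raise ValidationError("signal must be 1-D with at least 16 samples")
    if n_scales < 2:
        raise ValidationError("n_scales must be >= 2")
    # remove the DC component: at the smallest scales the discretized wavelet
    # is too coarse to cancel a large constant offset exactly
    signal = signal - signal.mean()
    freqs = np.geomspace(sample_rate_hz / 2.0, sample_rate_hz / signal.size, n_scales)
    wavelet = pywt.ContinuousWavelet(_WAVELET_NAME)
    scales = pywt.frequency2scale(wavelet, freqs / sample_rate_hz)
    coef, freqs_out = pywt.cwt(signal, scales, wavelet, sampling_period=1.0 / sample_rate_hz)
    return CWTSpectrum(
        magnitudes=np.abs(coef),
        frequencies_hz=freqs_out,
        sample_rate_hz=sample_rate_hz,
    )


def spectrum_pcc(
    s1: CWTSpectrum,
    s2: CWTSpectrum,
    split_hz: float = 450.0,
) -> tuple[float, float, float]:
    """Pearson correlation of two spectra: overall, low (< split) and high (>=).

    The band split defaults to the base-translocation rate: content above it
    reflects within-level detail, content below it the level structure itself.
    """
    if s1.magnitudes.shape != s2.magnitudes.shape:
        raise ValidationError("spectra must have the same shape")
    if not np.allclose(s1.frequencies_hz, s2.frequencies_hz):
        raise ValidationError("spectra must share the frequency axis")
    low = s1.frequencies_hz < split_hz
    high = ~low
    if not low.any() or not high.any():
        raise ValidationError(
            f"split at {split_hz} Hz leaves an empty band for this frequency axis"
        )

    def _pcc(x: np.ndarray, y: np.ndarray) -> float:
        x = x.ravel()
        y = y.ravel()
        if x.std() == 0 or y.std() == 0:
            raise ValidationError("correlation undefined for zero-variance spectrum part")
        if np.array_equal(x, y):
            return 1.0  # avoid rounding the self-correlation below 1
        return float(np.corrcoef(x, y)[0, 1])

    return (
        _pcc(s1.magnitudes, s2.magnitudes),
        _pcc(s1.magnitudes[low], s2.magnitudes[low]),
        _pcc(s1.magnitudes[high], s2.magnitudes[high]),
    )
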