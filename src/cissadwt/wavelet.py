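"""Four-level discrete wavelet filtering of the EOG carrier.

The EZ series (sum of flagged CiSSA components) still contains genuine EEG
detail alongside the blink waveform.  A 4-level Mallat cascade with the db4
wavelet splits it into a level-4 approximation — the 0..fs/32 band, about
0..3.9 Hz at 250 Hz, where the blink energy sits — and four detail bands.
Zeroing the approximation and inverting removes the blink carrier while the
detail bands return the retained EEG content to the clean signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt

from .core import ParameterError, as_samples

__all__ = [
    "WaveletDecomposition",
    "dwt4",
    "zero_approximation",
    "idwt",
    "remove_low_frequency",
]

DEFAULT_WAVELET = "db4"
DEFAULT_MODE = "symmetric"
DEFAULT_LEVELS = 4


@dataclass(frozen=True)
class WaveletDecomposition:
    """Mallat-cascade coefficients with the metadata needed to invert them.

    ``approximation`` holds the deepest-level coefficients (A_L); ``details``
    holds D1..DL ordered from finest (level 1) to coarsest (level L).
    """

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]  # D1 (finest) .. DL (coarsest)
    wavelet_name: str
    padding_mode: str
    original_length: int

    @property
    def levels(self) -> int:
        return len(self.details)


def dwt4(
    series,
    wavelet_name: str = DEFAULT_WAVELET,
    padding_mode: str = DEFAULT_MODE,
    levels: int = DEFAULT_LEVELS,
) -> WaveletDecomposition:
    """Multilevel DWT of a series (default: 4-level db4).

    Raises an explicit error when the series is too short to support the
    requested depth, suggesting fewer levels.
    """
    v = as_samples(series)
    w = pywt.Wavelet(wavelet_name)
    if levels < 1:
        raise ParameterError(f"levels must be >= 1, got {levels}")
    # hard limit: every cascade level needs at least one coefficient; pywt's
    # dwt_max_level guideline is stricter but reconstruction stays exact
    if v.size < 2**levels:
        max_lev = max(int(np.floor(np.log2(v.size))), 0)
        raise ParameterError(
            f"series of length {v.size} supports at most {max_lev} levels with "
            f"{wavelet_name}; requested {levels} — use fewer levels"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # boundary-effect notice
        coeffs = pywt.wavedec(v, w, mode=padding_mode, level=levels)
    approx, details_coarse_to_fine = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        approximation=approx,
        details=tuple(reversed(details_coarse_to_fine)),  # store D1..DL
        wavelet_name=wavelet_name,
        padding_mode=padding_mode,
        original_length=v.size,
    )


def zero_approximation(decomp: WaveletDecomposition) -> WaveletDecomposition:
    """Replace the deepest approximation with zeros; details untouched."""
    return replace(decomp, approximation=np.zeros_like(decomp.approximation))


def _coeff_list(decomp: WaveletDecomposition) -> list[np.ndarray]:
    return [decomp.approximation, *reversed(decomp.details)]


def idwt(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse Mallat cascade: upsample-and-filter back to a series.

    Restores exactly ``original_length`` samples; an unmodified
    decomposition reproduces its input to floating-point accuracy (the db
    wavelets are orthogonal).  The reconstruction is additive across
    coefficient sets: inverting A_L alone plus each D_m alone sums to the
    full inverse.
    """
    coeffs = _coeff_list(decomp)
    w = pywt.Wavelet(decomp.wavelet_name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        expected = pywt.wavedec(
            np.zeros(decomp.original_length), w, mode=decomp.padding_mode,
            level=decomp.levels,
        )
    for c, e in zip(coeffs, expected):
        if c.shape != e.shape:
            raise ParameterError(
                f"coefficient length {c.shape} inconsistent with original_length="
                f"{decomp.original_length} under mode {decomp.padding_mode!r} "
                f"(expected {e.shape})"
            )
    out = pywt.waverec(coeffs, w, mode=decomp.padding_mode)
    return out[: decomp.original_length]


def remove_low_frequency(
    series,
    wavelet_name: str = DEFAULT_WAVELET,
    padding_mode: str = DEFAULT_MODE,
    levels: int = DEFAULT_LEVELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a series into (residual, removed) about the level-L band edge.

    ``residual`` is the series rebuilt from detail coefficients only (the
    approximation zeroed); ``removed = series - residual`` is the low-band
    part, approximately 0..fs/2**(L+1) Hz.  The two halves sum back to the
    input exactly by construction.
    """
    v = as_samples(series)
    residual = idwt(zero_approximation(dwt4(v, wavelet_name, padding_mode, levels)))
    removed = v - residual
    return residual, removed
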