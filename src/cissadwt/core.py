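"""Core containers and errors shared across the package."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A parameter violates a documented precondition."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. zero variance)."""


class DegenerateSignalWarning(UserWarning):
    """Emitted when a degenerate (constant / zero-variance) signal is handled
    by a documented fallback instead of an error."""


class FallbackSelectionWarning(UserWarning):
    """Emitted when no component passes both thresholds and the lowest-
    frequency component is flagged by policy."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : ndarray of shape (t,)
        Samples, conventionally in microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ParameterError(f"values must be 1-D, got shape {v.shape}")
        if v.size < 2:
            raise ParameterError(f"need at least 2 samples, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise ParameterError("values must be finite")
        if not (self.fs > 0):
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "values", v)

    @property
    def t(self) -> int:
        """Length in samples."""
        return self.values.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.t / self.fs

    def __len__(self) -> int:
        return self.t


def as_samples(x, name: str = "series") -> np.ndarray:
    """Coerce a TimeSeries or array-like to a finite 1-D float array."""
    if isinstance(x, TimeSeries):
        return x.values
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ParameterError(f"{name} must be 1-D, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ParameterError(f"{name} must be finite")
    return v


def warn_degenerate(message: str) -> None:
    warnings.warn(message, DegenerateSignalWarning, stacklevel=3)
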