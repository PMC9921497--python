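"""Kurtosis/energy scoring and EOG component selection.

Blink artifacts are sparse, high-amplitude pulses, so the components that
carry them have heavy-tailed amplitude distributions (high kurtosis) and,
because blinks dwarf the background EEG, high energy.  A component is
flagged as EOG-related when BOTH scores exceed their thresholds; the flagged
components are summed into the EZ series handed to the wavelet filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import ParameterError, UndefinedMetricError, FallbackSelectionWarning, as_samples
from .cissa import ComponentSet

__all__ = [
    "ComponentScores",
    "ArtifactMask",
    "ArtifactSelector",
    "kurtosis",
    "energy",
    "select_artifact_components",
]


def kurtosis(series, formula: str = "ratio") -> float:
    """Kurtosis of a series: the standardized fourth central moment m4/m2**2.

    Gaussian data gives ~3; a blink train gives much more, since a few large
    pulses dominate the fourth moment.  ``formula="subtractive"`` computes
    the scale-dependent variant ``m4 - m2**2`` instead (kept for fidelity
    experiments; not recommended).
    """
    v = as_samples(series)
    if v.size < 4:
        raise ParameterError(f"kurtosis needs >= 4 samples, got {v.size}")
    c = v - v.mean()
    m2 = np.mean(c**2)
    if m2 == 0.0:
        raise UndefinedMetricError("kurtosis undefined for zero-variance series")
    m4 = np.mean(c**4)
    if formula == "ratio":
        return float(m4 / m2**2)
    if formula == "subtractive":
        return float(m4 - m2**2)
    raise ParameterError(f"unknown kurtosis formula {formula!r}")


def energy(series) -> float:
    """Signal energy: sum of squared samples (raw, not mean-removed)."""
    v = as_samples(series)
    return float(v @ v)


@dataclass(frozen=True)
class ComponentScores:
    """Per-component kurtosis and energy with the central moments used."""

    kurtosis: np.ndarray
    energy: np.ndarray
    m2: np.ndarray
    m4: np.ndarray


@dataclass(frozen=True)
class ArtifactMask:
    """Selection result: per-component flags, thresholds and the EZ stack."""

    flags: np.ndarray  # (G,) bool
    Kt: float
    Et: float
    scores: ComponentScores
    ez_indices: tuple[int, ...]
    ez: np.ndarray  # element-wise sum of flagged components, length t
    fallback_used: bool


class ArtifactSelector(BaseEstimator):
    """Flag EOG-related components by dual kurtosis/energy thresholding.

    Parameters
    ----------
    kt, et : float or "auto", default "auto"
        Kurtosis and energy thresholds.  "auto" uses mean + 1 std of the
        score across components, matching the relative notion that artifact
        components score "much higher" than the rest without per-subject
        tuning.
    kurtosis_formula : {"ratio", "subtractive"}
        See :func:`kurtosis`.
    min_energy_ratio : float, default 1e-3
        Components whose energy is below this fraction of the maximum
        component energy are treated as zero-variance: excluded from the
        auto-threshold statistics and never flagged.

    Attributes
    ----------
    flags_ : bool ndarray of shape (G,)
        True where a component is EOG-related.
    kt_, et_ : float
        Thresholds actually applied.
    ez_ : ndarray of shape (t,)
        Element-wise sum of the flagged components.
    fallback_used_ : bool
        True when no component passed both thresholds and the lowest-
        frequency component was flagged by policy (a warning is emitted:
        blinks live in the first one or two components, and a clean
        recording should remain auditable).
    """

    def __init__(self, kt="auto", et="auto", kurtosis_formula: str = "ratio",
                 min_energy_ratio: float = 1e-3):
        self.kt = kt
        self.et = et
        self.kurtosis_formula = kurtosis_formula
        self.min_energy_ratio = min_energy_ratio

    def fit(self, components, y=None) -> "ArtifactSelector":
        comps = components.components if isinstance(components, ComponentSet) else np.asarray(components, dtype=float)
        if comps.ndim != 2 or comps.shape[0] < 2:
            raise ParameterError("need >= 2 components (rows)")
        centered = comps - comps.mean(axis=1, keepdims=True)
        m2 = np.mean(centered**2, axis=1)
        if np.all(m2 == 0.0):
            raise UndefinedMetricError("all components have zero variance")
        m4 = np.mean(centered**4, axis=1)
        en = np.einsum("ij,ij->i", comps, comps)
        # components holding a negligible share of the energy (bands beyond
        # the signal's bandwidth, or spiky sub-0.1% leakage of a pulse) can
        # never be the artifact carrier; their kurtosis must not shape the
        # auto thresholds, so they are excluded from scoring and candidacy
        live = en > self.min_energy_ratio * en.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.kurtosis_formula == "ratio":
                kurt = np.where(live & (m2 > 0.0), m4 / np.where(m2 > 0, m2, 1.0) ** 2, np.nan)
            elif self.kurtosis_formula == "subtractive":
                kurt = np.where(live & (m2 > 0.0), m4 - m2**2, np.nan)
            else:
                raise ParameterError(f"unknown kurtosis formula {self.kurtosis_formula!r}")

        finite = np.isfinite(kurt)
        kt = float(np.mean(kurt[finite]) + np.std(kurt[finite])) if self.kt == "auto" else float(self.kt)
        et = float(np.mean(en[live]) + np.std(en[live])) if self.et == "auto" else float(self.et)

        flags = finite & (kurt > kt) & (en > et)
        fallback = not flags.any()
        if fallback:
            flags = flags.copy()
            flags[0] = True
            warnings.warn(
                "no component exceeded both thresholds; flagging the lowest-"
                "frequency component by fallback policy",
                FallbackSelectionWarning,
                stacklevel=2,
            )

        self.scores_ = ComponentScores(kurtosis=kurt, energy=en, m2=m2, m4=m4)
        self.flags_ = flags
        self.kt_ = kt
        self.et_ = et
        self.ez_ = comps[flags].sum(axis=0)
        self.fallback_used_ = fallback
        return self

    def mask(self) -> ArtifactMask:
        """Fitted selection as an immutable ArtifactMask."""
        return ArtifactMask(
            flags=self.flags_,
            Kt=self.kt_,
            Et=self.et_,
            scores=self.scores_,
            ez_indices=tuple(int(i) for i in np.flatnonzero(self.flags_)),
            ez=self.ez_,
            fallback_used=self.fallback_used_,
        )


def select_artifact_components(components, Kt="auto", Et="auto") -> ArtifactMask:
    """Thin wrapper over :class:`ArtifactSelector`."""
    return ArtifactSelector(kt=Kt, et=Et).fit(components).mask()
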