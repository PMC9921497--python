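"""Evaluation metrics for artifact removal.

With ground truth available (synthetic mixtures) the artifact estimate is
scored by RRMSE and Pearson correlation against the true blink train, and
SAR against the estimation error.  On real recordings there is no ground
truth; the real-data SAR convention scores the raw signal against the
change the cleaner made to it, and the band MAE compares power spectra of
the contaminated and rectified signals over a band (alpha, 8-13 Hz, by
default) to quantify how much genuine EEG rhythm was disturbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import ParameterError, UndefinedMetricError, as_samples

__all__ = ["MetricsReport", "rrmse", "cc", "sar", "sar_real", "mae_band", "evaluate"]

ALPHA_BAND = (8.0, 13.0)


def _pair(a, b, name_a: str, name_b: str) -> tuple[np.ndarray, np.ndarray]:
    va, vb = as_samples(a, name_a), as_samples(b, name_b)
    if va.size != vb.size:
        raise ParameterError(f"{name_a} and {name_b} must have equal length "
                             f"({va.size} != {vb.size})")
    return va, vb


def rrmse(k, k_hat) -> float:
    """Relative root-mean-square error of the artifact estimate, in percent.

    ``RMS(k - k_hat) / RMS(k) * 100``: 0 for a perfect estimate, 100 for the
    null estimate.
    """
    vk, vkh = _pair(k, k_hat, "k", "k_hat")
    if vk.size < 2:
        raise ParameterError("need length >= 2")
    denom = np.sqrt(np.mean(vk**2))
    if denom == 0.0:
        raise UndefinedMetricError("RRMSE undefined: ground-truth artifact has zero energy")
    return float(np.sqrt(np.mean((vk - vkh) ** 2)) / denom * 100.0)


def cc(k, k_hat) -> float:
    """Pearson correlation coefficient between estimate and ground truth."""
    vk, vkh = _pair(k, k_hat, "k", "k_hat")
    if vk.std() == 0.0 or vkh.std() == 0.0:
        raise UndefinedMetricError("CC undefined for zero-variance input")
    return float(np.corrcoef(vk, vkh)[0, 1])


def sar(k, k_hat) -> float:
    """Signal-to-artifact ratio in dB: ``10*log10(sigma(k)/sigma(k_hat - k))``.

    Higher is better; a perfect estimate has no residual and returns +inf
    (documented sentinel).
    """
    vk, vkh = _pair(k, k_hat, "k", "k_hat")
    resid_sd = np.std(vkh - vk)
    if resid_sd == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.std(vk) / resid_sd))


def sar_real(s, q_hat) -> float:
    """Real-data SAR (no ground truth): ``10*log10(sigma(s)/sigma(q_hat - s))``.

    The raw signal stands in for the artifact reference and the change made
    by cleaning stands in for the estimation error.
    """
    vs, vq = _pair(s, q_hat, "s", "q_hat")
    resid_sd = np.std(vq - vs)
    if resid_sd == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.std(vs) / resid_sd))


def _welch_psd(v: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(256, v.size)
    return scipy.signal.welch(v, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2)


def mae_band(s, q_hat, fs: float, band: tuple[float, float] = ALPHA_BAND) -> float:
    """Mean absolute difference of Welch power spectra over a band.

    Near 0 when cleaning leaves the band's EEG rhythm intact.  Default band
    is alpha (8-13 Hz); the PSD uses Welch with 256-sample Hann segments at
    50% overlap.
    """
    vs, vq = _pair(s, q_hat, "s", "q_hat")
    a, b = band
    if not (0.0 < a < b < fs / 2.0):
        raise ParameterError(f"band {band} must lie inside (0, fs/2) = (0, {fs / 2})")
    f, ps = _welch_psd(vs, fs)
    _, pq = _welch_psd(vq, fs)
    in_band = (f >= a) & (f <= b)
    if not in_band.any():
        raise ParameterError(f"no PSD bins inside band {band}")
    return float(np.mean(np.abs(ps[in_band] - pq[in_band])))


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of the four evaluation metrics for one cleaned signal."""

    rrmse: float | None
    cc: float | None
    sar: float | None
    mae: float
    band: tuple[float, float]
    psd_method: str = "welch-256-hann-50%"

    def to_dict(self) -> dict:
        return {
            "rrmse_percent": self.rrmse,
            "cc": self.cc,
            "sar_db": self.sar,
            "mae_band_power": self.mae,
            "band_hz": list(self.band),
            "psd_method": self.psd_method,
        }


def evaluate(
    s,
    q_hat,
    k_hat,
    fs: float,
    k=None,
    band: tuple[float, float] = ALPHA_BAND,
) -> MetricsReport:
    """Score a cleaning run.

    With ground truth ``k``, RRMSE/CC/SAR are computed on the artifact
    estimate; without it, SAR falls back to the real-data convention and
    RRMSE/CC are None.  MAE is always computed on (s, q_hat) spectra.
    """
    if k is not None:
        return MetricsReport(
            rrmse=rrmse(k, k_hat),
            cc=cc(k, k_hat),
            sar=sar(k, k_hat),
            mae=mae_band(s, q_hat, fs, band),
            band=band,
        )
    return MetricsReport(
        rrmse=None,
        cc=None,
        sar=sar_real(s, q_hat),
        mae=mae_band(s, q_hat, fs, band),
        band=band,
    )
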