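"""Synthetic EEG, blink artifacts, and contaminated mixtures.

The mixing model is ``s = q + p*k``: ground-truth EEG ``q``, blink artifact
``k``, and a scalar mixing constant ``p`` controlling artifact severity
(p > 1 means a more prominent artifact / lower SNR).  The generator makes
the whole pipeline testable with no external recordings:

* ``gen_eeg`` — zero-mean colored noise with a 1/f background and an
  alpha-band (10 Hz) resonance, band-limited to 0.5-45 Hz, unit variance.
* ``gen_eog`` — a train of smooth positive blink pulses, roughly every five
  seconds, whose energy sits in the 0.5-12 Hz band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ParameterError, TimeSeries

__all__ = ["BlinkParams", "MixingModel", "gen_eeg", "gen_eog", "mix", "make_benchmark"]

DEFAULT_P_GRID = (0.5, 1.0, 1.25, 1.5)


@dataclass(frozen=True)
class BlinkParams:
    """Parameters of the blink-train generator.

    rate : blinks per second (default 0.2 — one blink every five seconds).
    width : single-pulse duration in seconds.
    amplitude : pulse peak in units of EEG standard deviation; frontal blink
        deflections are several-fold the background-EEG RMS, hence the
        default of 8.
    shape : "halfsine2" (squared half-sine) or "gamma".
    timing : "jittered" (regular 1/rate spacing with uniform jitter) or
        "poisson".
    jitter : fraction of the mean interval used as the jitter half-width.
    """

    rate: float = 0.2
    width: float = 0.35
    amplitude: float = 8.0
    shape: str = "halfsine2"
    timing: str = "jittered"
    jitter: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.rate > 0 and self.width > 0):
            raise ParameterError("rate and width must be positive")
        if self.rate * self.width >= 1.0:
            raise ParameterError("rate*width must be < 1 (non-overlapping blinks)")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class MixingModel:
    """A contaminated EEG mixture ``s = q + p*k`` with its ground truth."""

    q: TimeSeries
    k: TimeSeries
    p: float
    s: TimeSeries


def gen_eeg(t: int, fs: float = 250.0, seed: int | None = None) -> TimeSeries:
    """Generate a unit-variance synthetic background EEG.

    Spectral shaping in the frequency domain: Gaussian white noise is
    weighted by ``1/f**(gamma/2)`` (gamma = 1) inside the 0.5-45 Hz pass
    band, with a second-order high-pass rolloff below 1.5 Hz (emulating the
    acquisition high-pass and the scarcity of sub-delta power in awake
    recordings), plus a Gaussian bump centered at 10 Hz emulating the
    dominant eyes-closed alpha rhythm; then inverse-transformed, de-meaned
    and scaled to unit variance.  The resulting relative band powers
    (delta ~7%, theta ~6%, alpha ~78%) describe an alpha-dominant awake
    record.  Deterministic per seed.
    """
    if t < 100:
        raise ParameterError(f"need t >= 100 samples, got {t}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(t)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(t, d=1.0 / fs)
    gamma = 1.0
    with np.errstate(divide="ignore"):
        shape = np.where(f > 0, f, np.inf) ** (-gamma / 2.0)
        shape /= np.sqrt(1.0 + np.where(f > 0, 1.5 / f, np.inf) ** 4)
    shape[~((f >= 0.5) & (f <= 45.0))] = 0.0
    # alpha resonance: amplitude bump at 10 Hz, clearly above the 1/f slope
    alpha = 2.0 * np.exp(-0.5 * ((f - 10.0) / 1.0) ** 2)
    alpha[~((f >= 0.5) & (f <= 45.0))] = 0.0
    x = np.fft.irfft(spec * (shape + alpha), n=t)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return TimeSeries(values=x, fs=fs)


def _pulse(width_samples: int, shape: str) -> np.ndarray:
    n = np.arange(width_samples)
    if shape == "halfsine2":
        return np.sin(np.pi * (n + 0.5) / width_samples) ** 2
    if shape == "gamma":
        # gamma-like pulse: fast rise, slower decay, normalized to unit peak
        tt = (n + 0.5) / width_samples
        p = tt**2 * np.exp(-6.0 * tt)
        return p / p.max()
    raise ParameterError(f"unknown pulse shape {shape!r}")


def gen_eog(t: int, fs: float = 250.0, params: BlinkParams | None = None) -> TimeSeries:
    """Generate a blink-artifact train.

    Smooth positive pulses of the given width are placed at jittered-regular
    (default) or Poisson times with mean interval ``1/rate``; the pulse
    family keeps essentially all energy below 12 Hz.
    """
    params = params or BlinkParams()
    wid = int(round(params.width * fs))
    if t < wid:
        raise ParameterError(f"t={t} shorter than one pulse ({wid} samples)")
    rng = np.random.default_rng(params.seed)
    duration = t / fs
    mean_iv = 1.0 / params.rate
    if params.timing == "jittered":
        base = np.arange(mean_iv / 2.0, duration, mean_iv)
        times = base + rng.uniform(-params.jitter * mean_iv, params.jitter * mean_iv, base.size)
    elif params.timing == "poisson":
        times = np.cumsum(rng.exponential(mean_iv, size=max(4, int(4 * duration * params.rate))))
        times = times[times < duration]
    else:
        raise ParameterError(f"unknown timing model {params.timing!r}")
    x = np.zeros(t)
    pulse = params.amplitude * _pulse(wid, params.shape)
    for tc in times:
        start = int(round(tc * fs)) - wid // 2
        lo, hi = max(start, 0), min(start + wid, t)
        if hi > lo:
            x[lo:hi] += pulse[lo - start : hi - start]
    return TimeSeries(values=x, fs=fs)


def mix(q: TimeSeries, k: TimeSeries, p: float) -> MixingModel:
    """Form the contaminated mixture ``s = q + p*k`` (element-wise, exact)."""
    if q.t != k.t or q.fs != k.fs:
        raise ParameterError(
            f"q and k must share length and fs (got t={q.t}/{k.t}, fs={q.fs}/{k.fs})"
        )
    if p < 0:
        raise ParameterError(f"mixing constant p must be >= 0, got {p}")
    s = TimeSeries(values=q.values + p * k.values, fs=q.fs)
    return MixingModel(q=q, k=k, p=p, s=s)


def make_benchmark(
    n_trials: int = 50,
    p_values: tuple[float, ...] = DEFAULT_P_GRID,
    seed: int = 0,
    t: int = 2500,
    fs: float = 250.0,
    blink: BlinkParams | None = None,
    out_dir: str | Path | None = None,
):
    """Reproducible corpus of contaminated mixtures over a grid of p values.

    Returns ``(mixtures, manifest)`` where ``mixtures`` maps ``p`` to a list
    of :class:`MixingModel` and the manifest records every per-trial seed.
    With ``out_dir`` set, ground truth and mixtures are written as one text
    file per trial plus a JSON manifest.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    blink = blink or BlinkParams()
    master = np.random.default_rng(seed)
    trial_seeds = master.integers(0, 2**31 - 1, size=(n_trials, 2))
    mixtures: dict[float, list[MixingModel]] = {float(p): [] for p in p_values}
    manifest = {
        "master_seed": int(seed),
        "t": int(t),
        "fs": float(fs),
        "p_values": [float(p) for p in p_values],
        "blink_params": {k: v for k, v in asdict(blink).items() if k != "seed"},
        "trials": [],
        "files": [],
    }
    for i in range(n_trials):
        eeg_seed, eog_seed = int(trial_seeds[i, 0]), int(trial_seeds[i, 1])
        q = gen_eeg(t, fs, seed=eeg_seed)
        k = gen_eog(t, fs, params=BlinkParams(**{**asdict(blink), "seed": eog_seed}))
        manifest["trials"].append({"trial": i, "eeg_seed": eeg_seed, "eog_seed": eog_seed})
        for p in p_values:
            mixtures[float(p)].append(mix(q, k, float(p)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for p, models in mixtures.items():
            for i, m in enumerate(models):
                stem = f"trial{i:03d}_p{p:g}"
                for tag, ts in (("q", m.q), ("k", m.k), ("s", m.s)):
                    path = out / f"{stem}_{tag}.csv"
                    np.savetxt(path, ts.values, header=tag, comments="", fmt="%.17g")
                    manifest["files"].append(path.name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return mixtures, manifest
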