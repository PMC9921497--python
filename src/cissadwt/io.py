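"""Reading and writing EEG signals.

Two on-disk formats are supported: delimited text (one column per channel,
optional single header row — lossless at full decimal precision) and the
European Data Format (EDF), the clinical interchange standard.  EDF files
are read through :mod:`mne`; writing uses the compact 16-bit EDF encoder in
this module, which records the physical range so quantization error is
bounded by ``(phys_max - phys_min) / 2**16``.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ParameterError, TimeSeries

__all__ = ["RecordHeader", "read_signal", "write_signal", "write_edf", "atomic_write_text"]


class FormatError(ParameterError):
    """Unknown or malformed file format."""


class ChannelError(ParameterError):
    """Requested channel missing from the record."""


@dataclass(frozen=True)
class RecordHeader:
    """Channel labels, rates and units of a multichannel record."""

    labels: tuple[str, ...]
    fs: tuple[float, ...]
    units: tuple[str, ...]
    source_format: str

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ParameterError(f"channel labels must be unique: {self.labels}")
        if any(f <= 0 for f in self.fs):
            raise ParameterError("all sampling rates must be > 0")


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".tsv", ".txt", ".dat"):
        return "text"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _read_text(path: Path, fs: float | None, channel) -> tuple[TimeSeries, RecordHeader]:
    if fs is None:
        raise ParameterError("text files carry no sampling rate; pass fs explicitly")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    # headerless files: first row parsed as labels would be numeric
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
        df.columns = [f"ch{i}" for i in range(df.shape[1])]
    except ValueError:
        pass
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise FormatError(f"{path} contains non-numeric cells")
    labels = tuple(str(c) for c in df.columns)
    if channel is None:
        channel = labels[0]
    key = labels[int(channel)] if isinstance(channel, int) else str(channel)
    if key not in labels:
        raise ChannelError(f"channel {channel!r} not in {labels}")
    header = RecordHeader(labels=labels, fs=(fs,) * len(labels),
                          units=("uV",) * len(labels), source_format="text")
    return TimeSeries(values=df[key].to_numpy(dtype=float), fs=fs), header


def _read_edf(path: Path, fs: float | None, channel) -> tuple[TimeSeries, RecordHeader]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if channel is None:
        channel = labels[0]
    key = labels[int(channel)] if isinstance(channel, int) else str(channel)
    if key not in labels:
        raise ChannelError(f"channel {channel!r} not in {labels}")
    rate = float(fs if fs is not None else raw.info["sfreq"])
    data = raw.get_data(picks=[labels.index(key)])[0] * 1e6  # mne loads EEG in volts
    header = RecordHeader(labels=labels, fs=(rate,) * len(labels),
                          units=("uV",) * len(labels), source_format="edf")
    return TimeSeries(values=np.asarray(data, dtype=float), fs=rate), header


def read_signal(path, format: str = "auto", channel=None, fs: float | None = None):
    """Read one channel from a delimited-text or EDF file.

    Returns ``(TimeSeries, RecordHeader)``.  ``channel`` selects by label or
    0-based index (default: first channel); ``fs`` overrides (text:
    required, EDF: optional) the sampling rate.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "text":
        return _read_text(path, fs, channel)
    if fmt == "edf":
        return _read_edf(path, fs, channel)
    raise FormatError(f"unknown format {fmt!r}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signals: list[np.ndarray], labels: list[str], fs: float) -> None:
    """Write channels to an EDF file (16-bit, one data record).

    Physical min/max are taken from the data, so the quantization step is
    the physical range divided by 2**16.
    """
    n_sig = len(signals)
    if n_sig == 0 or any(len(s) == 0 for s in signals):
        raise ParameterError("need at least one non-empty signal")
    t = len(signals[0])
    if any(len(s) != t for s in signals):
        raise ParameterError("all channels must share a length")
    duration = t / fs
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_sig), 8),
        _edf_field("", 44),
        _edf_field(1, 8),
        _edf_field(f"{duration:.6g}", 8),
        _edf_field(n_sig, 4),
    ])
    phys_min, phys_max, dig = [], [], []
    for sig in signals:
        v = np.asarray(sig, dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi - lo == 0.0:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (v - lo) / (hi - lo) * 65535.0 - 32768.0
        dig.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))
    fields = [
        [_edf_field(lab, 16) for lab in labels],
        [_edf_field("", 80)] * n_sig,
        [_edf_field("uV", 8)] * n_sig,
        [_edf_field(f"{lo:.8g}"[:8], 8) for lo in phys_min],
        [_edf_field(f"{hi:.8g}"[:8], 8) for hi in phys_max],
        [_edf_field(-32768, 8)] * n_sig,
        [_edf_field(32767, 8)] * n_sig,
        [_edf_field("", 80)] * n_sig,
        [_edf_field(t, 8)] * n_sig,
        [_edf_field("", 32)] * n_sig,
    ]
    payload = b"".join(b"".join(f) for f in fields) + b"".join(d.tobytes() for d in dig)
    _atomic_write_bytes(Path(path), header + payload)


def write_signal(series: TimeSeries, path, format: str = "auto", label: str = "eeg") -> None:
    """Write a TimeSeries to text (lossless) or EDF (16-bit quantized)."""
    path = Path(path)
    if series.t < 2:
        raise ParameterError("refusing to write an empty/degenerate series")
    fmt = _detect_format(path, format)
    if fmt == "text":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        body = label + "\n" + "\n".join(repr(float(v)) for v in series.values) + "\n"
        atomic_write_text(path, body)
        del sep  # single-channel text has no delimiter in the body
    elif fmt == "edf":
        write_edf(path, [series.values], [label], series.fs)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def atomic_write_text(path: Path, text: str) -> None:
    """Write text via a temp file + rename so failures never leave partial
    output."""
    _atomic_write_bytes(Path(path), text.encode())


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
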