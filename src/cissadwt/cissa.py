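"""Circulant singular spectrum analysis (CiSSA).

Decomposes a time series into frequency-ordered additive components.  Unlike
basic SSA, whose eigenvectors depend on the data, the circulant variant ties
eigenvector ``b`` to the fixed frequency ``(b-1)/R`` cycles/sample: the
second-moment matrix is approximated by a circulant matrix built from sample
autocovariances, whose eigenvectors are the Fourier basis.  Grouping the
conjugate-pair eigenvectors therefore yields one real component per frequency
band, and the components sum exactly to the input because the group
projectors partition the identity.

The pipeline is: embed the series into an R x S Hankel trajectory matrix,
build the circulant spectrum, project the trajectory matrix onto each
conjugate-pair subspace, and hankelize (anti-diagonal average) each projected
matrix back to a series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from .core import ParameterError, TimeSeries, as_samples, warn_degenerate

__all__ = [
    "CirculantSpectrum",
    "ComponentSet",
    "CiSSA",
    "embed",
    "circulant_first_row",
    "circulant_eigens",
    "group_projectors",
    "hankelize",
    "cissa",
    "n_groups",
]


def n_groups(R: int) -> int:
    """Number of grouped components for window length ``R``.

    One zero-frequency group, ``floor((R-1)/2)`` conjugate-pair groups and,
    for even ``R``, a Nyquist singleton: ``R//2 + 1`` for even ``R`` and
    ``(R - 1)//2 + 1`` for odd ``R``.
    """
    return R // 2 + 1 if R % 2 == 0 else (R - 1) // 2 + 1


def embed(x, R: int) -> np.ndarray:
    """Build the R x S Hankel trajectory matrix of lagged windows.

    ``entries[i, j] = x[i + j]`` with ``S = t - R + 1``; every anti-diagonal
    is constant.
    """
    v = as_samples(x)
    t = v.size
    if not (2 <= R <= t - 1):
        raise ParameterError(
            f"window length R={R} out of range [2, t-1] for series of length t={t}"
        )
    return scipy.linalg.hankel(v[:R], v[R - 1 :])


def circulant_first_row(x, R: int) -> np.ndarray:
    """First row of the circulant second-moment matrix.

    Convex combination of biased sample autocovariances at complementary
    lags: ``M[n] = ((R-n)/R) * acov[n] + (n/R) * acov[R-n]`` for
    ``n = 0 .. R-1``, with the autocovariance mean-removed and divided by t.
    ``M[0]`` is the biased sample variance.  A constant (zero-variance) input
    yields an all-zero row and a warning.
    """
    v = as_samples(x)
    t = v.size
    if R > t - 1:
        raise ParameterError(f"R={R} must be <= t-1={t - 1}")
    c = v - v.mean()
    if np.allclose(c, 0.0):
        warn_degenerate("constant series: circulant row is all zero")
        return np.zeros(R)
    # biased autocovariances at lags 0..R-1 (R-n stays within 1..R-1 for n>=1)
    acov = np.array([c[: t - m] @ c[m:] for m in range(R)]) / t
    n = np.arange(R)
    row = ((R - n) / R) * acov[n]
    row[1:] += (n[1:] / R) * acov[R - n[1:]]
    return row


@dataclass(frozen=True)
class CirculantSpectrum:
    """Eigenstructure of the circulant second-moment matrix.

    ``eigenvalues[b-1]`` is the DFT of the first row at frequency
    ``(b-1)/R``; ``eigenvectors[:, b-1]`` is the unit-norm Fourier vector
    ``R**-0.5 * exp(-2i*pi*(b-1)*k/R)``.  Eigenvalues at paired indices
    ``b`` and ``R+2-b`` coincide (PSD symmetry) and their eigenvectors are
    complex conjugates.
    """

    first_row: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (R, R) complex, columns are eigenvectors
    frequencies: np.ndarray  # (b-1)/R in cycles/sample

    @property
    def R(self) -> int:
        return self.first_row.size


def circulant_eigens(first_row) -> CirculantSpectrum:
    """Eigendecomposition of the circulant matrix with the given first row.

    The eigenvalues are the DFT of the first row; the imaginary residue must
    vanish (checked to 1e-9 relative) because the row encodes a symmetric
    circulant.
    """
    row = np.asarray(first_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise ParameterError("first_row must be 1-D with length >= 2")
    if not np.all(np.isfinite(row)):
        raise ParameterError("first_row must be finite")
    R = row.size
    lam = np.fft.fft(row)
    scale = max(np.max(np.abs(lam)), 1.0)
    if np.max(np.abs(lam.imag)) > 1e-9 * scale:
        raise ParameterError("circulant eigenvalues have non-negligible imaginary part")
    k = np.arange(R)
    # columns: j_b = R^{-1/2} exp(-2i pi (b-1) k / R)
    vecs = np.exp(-2j * np.pi * np.outer(k, k) / R) / np.sqrt(R)
    return CirculantSpectrum(
        first_row=row,
        eigenvalues=lam.real.copy(),
        eigenvectors=vecs,
        frequencies=k / R,
    )


def group_projectors(spectrum: CirculantSpectrum) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Conjugate-pair grouping projectors onto real frequency subspaces.

    Returns ``(A_b, P_b)`` pairs where ``A_b`` is the 1-based index group --
    ``{1}``, ``{b, R+2-b}`` for ``b = 2..``, and ``{R/2+1}`` for even R --
    and ``P_b`` is the real symmetric projector ``j_b j_b^H + conj`` (rank 2
    for pairs, rank 1 for the zero-frequency and Nyquist singletons).  The
    projectors are idempotent, mutually orthogonal, and sum to the identity.
    """
    R = spectrum.R
    V = spectrum.eigenvectors
    groups: list[tuple[tuple[int, ...], np.ndarray]] = []
    for b in range(1, R // 2 + 2 if R % 2 == 0 else (R - 1) // 2 + 2):
        u = V[:, b - 1]
        if b == 1 or (R % 2 == 0 and b == R // 2 + 1):
            P = np.real(np.outer(u, u.conj()))
            groups.append(((b,), P))
        else:
            P = 2.0 * np.real(np.outer(u, u.conj()))
            groups.append(((b, R + 2 - b), P))
    return groups


def hankelize(M) -> np.ndarray:
    """Anti-diagonal (secondary diagonal) averaging of a matrix to a series.

    ``out[k]`` is the mean of all entries ``M[i, j]`` with ``i + j = k``;
    the output has length ``R + S - 1``.  This is the adjoint-like inverse of
    embedding: applied to a Hankel matrix built from ``y`` it returns ``y``.
    """
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ParameterError("hankelize expects a non-empty 2-D matrix")
    R, S = A.shape
    t = R + S - 1
    sums = np.zeros(t)
    for i in range(R):
        sums[i : i + S] += A[i]
    counts = np.minimum(np.minimum(np.arange(1, t + 1), t - np.arange(t)), min(R, S))
    return sums / counts


@dataclass(frozen=True)
class ComponentSet:
    """Frequency-ordered additive components of a series.

    ``components[g]`` is the length-t reconstruction of group ``g``;
    components sum to the input.  ``center_frequencies`` are in Hz
    (``(b-1)/R * fs`` for the group's representative index ``b``), strictly
    increasing from 0.
    """

    components: np.ndarray  # (G, t)
    center_frequencies: np.ndarray  # (G,) Hz
    group_index_sets: tuple[tuple[int, ...], ...]
    R: int
    source_length: int
    fs: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self, which: Sequence[int] | None = None) -> np.ndarray:
        """Sum of the selected components (all of them by default)."""
        if which is None:
            return self.components.sum(axis=0)
        idx = np.asarray(list(which), dtype=int)
        return self.components[idx].sum(axis=0)


class CiSSA(BaseEstimator):
    """Circulant SSA decomposition estimator.

    Fits the circulant spectrum of a single series and exposes the grouped
    reconstructed components, scikit-learn style.

    Parameters
    ----------
    window : int, default 18
        Embedding window length R.  The tuned default yields 10 grouped
        components whose bands tile 0..Nyquist in steps of fs/R.
    fs : float, default 250.0
        Sampling rate in Hz, used only to report center frequencies.

    Attributes
    ----------
    components_ : ndarray of shape (G, t)
        Grouped reconstructed components, ordered by frequency.
    frequencies_ : ndarray of shape (G,)
        Center frequency of each group in Hz.
    groups_ : tuple of tuples
        1-based eigenvector index set of each group.
    spectrum_ : CirculantSpectrum
        Eigenvalues/eigenvectors of the circulant second-moment matrix.
    """

    def __init__(self, window: int = 18, fs: float = 250.0):
        self.window = window
        self.fs = fs

    def fit(self, x, y=None) -> "CiSSA":
        v = as_samples(x, "x")
        fs = x.fs if isinstance(x, TimeSeries) else self.fs
        R = int(self.window)
        A = embed(v, R)
        row = circulant_first_row(v, R)
        spectrum = circulant_eigens(row)
        groups = group_projectors(spectrum)
        comps = np.empty((len(groups), v.size))
        for g, (_, P) in enumerate(groups):
            comps[g] = hankelize(P @ A)
        self.spectrum_ = spectrum
        self.components_ = comps
        self.groups_ = tuple(idx for idx, _ in groups)
        self.frequencies_ = np.array([(idx[0] - 1) / R * fs for idx, _ in groups])
        self.n_components_ = len(groups)
        self.fs_ = fs
        return self

    def transform(self, x) -> np.ndarray:
        """Decompose ``x`` and return the (G, t) component array."""
        return self.fit(x).components_

    def component_set(self) -> ComponentSet:
        """Fitted decomposition as an immutable ComponentSet."""
        return ComponentSet(
            components=self.components_,
            center_frequencies=self.frequencies_,
            group_index_sets=self.groups_,
            R=int(self.window),
            source_length=self.components_.shape[1],
            fs=self.fs_,
        )


def cissa(x, R: int = 18, fs: float = 250.0) -> ComponentSet:
    """Decompose a series into frequency-ordered components (thin wrapper
    over the :class:`CiSSA` estimator)."""
    return CiSSA(window=R, fs=fs).fit(x).component_set()
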