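# Methods

## Signal model and pipeline

A recorded single-channel EEG segment is modeled as s = q + p·k: ground
truth brain activity q, an eye-blink (EOG) artifact k, and a nonnegative
mixing constant p describing artifact severity (p > 1: artifact dominates).
The cleaner estimates the pair (q̂, k̂) from s alone, in four linear
stages: CiSSA decomposition, kurtosis/energy component selection, 4-level
wavelet filtering of the selected components, and additive reconstruction.
Because every stage is linear, q̂ + k̂ = s holds to machine precision on
every run; this conservation is asserted throughout the test suite.

## Circulant SSA

For a segment of length t and window R, the trajectory matrix is the R×S
Hankel matrix of lagged windows (S = t − R + 1). Ordinary SSA
eigendecomposes the data-dependent second-moment matrix; the circulant
variant instead uses the circulant matrix with first row

    M̂ₙ = ((R−n)/R)·γ̂ₙ + (n/R)·γ̂₍R₋ₙ₎ ,   n = 0 … R−1,

where γ̂ₘ is the biased (divide by t), mean-removed sample autocovariance
at lag m. Its eigenvectors are the fixed Fourier basis
jᵦ = R^(−1/2)(1, e^(−i2π(b−1)/R), …), so eigenvector b is tied a priori to
frequency (b−1)/R cycles/sample and eigenvalues are the DFT of the first
row (a nonparametric PSD estimate). Conjugate pairs {b, R+2−b} are grouped
into real rank-2 projectors 2·Re(jᵦjᵦᴴ); the zero-frequency and (for even
R) Nyquist eigenvectors give rank-1 projectors. Each projected trajectory
matrix is diagonal-averaged (hankelized) back to a series.

Key consequences, all tested:

* the projectors partition the identity, so the components sum exactly to
  the input — "inverse CiSSA" is component summation, no separate inverse
  algorithm exists or is needed;
* the decomposition is deterministic (no eigensolver sign/phase
  ambiguity); a dense symmetric eigensolver is used only as a test oracle;
* a pure tone at a group frequency is recovered almost entirely (≥ 99% of
  its energy) inside that group.

Window default R = 18: at any sampling rate this tiles the spectrum into
10 bands of width fs/18 (≈ 13.9 Hz at 250 Hz), placing blink energy in the
first one or two components. A constant (zero-variance) segment
degenerates gracefully: the zero-frequency component carries the constant,
everything else is zero, and a warning is emitted.

## Component selection

Blinks are sparse, high-amplitude pulses, so blink-carrying components
have heavy-tailed amplitude distributions (kurtosis K = m₄/m₂² ≫ 3) and
large energy E = Σs². A component is flagged when K > Kt AND E > Et.
Defaults are relative, "auto" thresholds — mean + 1 standard deviation of
each score across components — so no per-subject tuning is required; both
can be overridden numerically.

Two guards matter in practice:

* Components holding less than 0.1% of the maximum component energy
  (`min_energy_ratio = 1e-3`) are excluded from the statistics and from
  candidacy. Bands beyond the EEG bandwidth contain only minute,
  time-localized leakage of the blink pulse whose kurtosis can reach the
  hundreds; without the guard those empty bands inflate Kt and the true
  blink component can fail it. A component that small can never be the
  artifact carrier, so excluding it loses nothing.
* If nothing passes both thresholds, the lowest-frequency component is
  flagged as a fallback (with a warning): blink energy sits in the first
  one or two components when present, and for a genuinely clean segment
  the wavelet stage then removes only that component's sub-4 Hz content,
  leaving the signal nearly intact. The warning keeps clean recordings
  auditable.

Kurtosis uses the classical standardized fourth moment m₄/m₂². A
scale-dependent subtractive variant m₄ − m₂² is available behind
`kurtosis_formula="subtractive"` for fidelity experiments only; it is not
recommended, being unnamed in the statistics literature and not scale-free.
Energy uses raw (not mean-removed) samples. Thresholds are applied per
segment, not per recording, so a drifting baseline in one frame cannot
mask a blink in another; this is configurable by cleaning segments
directly.

## Wavelet filtering

The flagged components are summed into the EZ series and decomposed by a
4-level Mallat cascade with the orthogonal Daubechies-4 (db4) wavelet. The
level-4 approximation occupies ≈ 0–fs/32 Hz — 0–3.9 Hz at fs = 250 Hz —
which is where blink energy concentrates; it is zeroed, and the inverse
cascade returns the detail content (genuine EEG riding on the flagged
components) to the clean signal. Users at other sampling rates should
adjust `levels` to keep the removed band near 0–4 Hz; the band is
fs/2^(levels+1).

Numerical choices: boundary extension defaults to symmetric (minimal edge
artifacts on biosignals); periodization is available and is the mode under
which coefficient energy equals signal energy exactly. Coefficient-length
bookkeeping for non-dyadic lengths (2500 is not a power of two) follows
the declared padding mode and is recorded in the decomposition object, so
inversion is unambiguous; inversion trims to the recorded original length.
The minimum input length for L levels is 2^L samples (each level keeps at
least one coefficient); the transform remains exactly invertible down to
that limit even where conventional depth guidelines would recommend fewer
levels.

## Segmentation

Records are cleaned in non-overlapping frames of Wd = fd·fs samples
(default fd = 10 s, fs = 250 Hz → 2500 samples). A trailing remainder is
kept as its own segment when it is long enough to decompose (≥ R + 1
samples) and merged into the previous frame otherwise. The per-segment
mean is removed before decomposition and restored to q̂, not k̂:
autocovariance estimation assumes centering, and the DC level belongs to
the EEG baseline, not to the blink.

## Metrics

* RRMSE = RMS(k − k̂)/RMS(k) × 100: 0 for a perfect artifact estimate,
  100 for the null estimate.
* CC: Pearson correlation between k̂ and k (should approach 1).
* SAR = 10·log₁₀(σ(k)/σ(k̂ − k)) in dB; when no ground truth exists the
  real-data convention SAR = 10·log₁₀(σ(s)/σ(q̂ − s)) is reported and
  labeled as such — the raw signal stands in for the artifact reference.
  A perfect estimate returns +inf as a documented sentinel.
* Band MAE: mean absolute difference of Welch power spectra (256-sample
  Hann segments, 50% overlap) over a band, default alpha = 8–13 Hz, the
  conventional definition. Near 0 when cleaning spares the band's rhythm.

CC and RRMSE are unit-invariant; SAR and MAE carry units (dB, power).
With synthetic ground truth, both framings — artifact recovery (k̂ vs k)
and EEG recovery (q̂ vs q) — are meaningful and the tests exercise both.

## Synthetic data generator

The generator emulates the study conditions: 2500-sample segments at
250 Hz, ground truth EEG mixed with a blink train at
p ∈ {0.5, 1, 1.25, 1.5}.

* **EEG**: Gaussian white noise spectrally shaped by 1/f^(γ/2) amplitude
  weighting (γ = 1) inside a 0.5–45 Hz passband, a second-order high-pass
  rolloff below 1.5 Hz (acquisition high-pass; awake recordings carry
  little sub-delta power), and a Gaussian 10 Hz alpha bump (amplitude
  weight 2.0, σ = 1 Hz), then normalized to zero mean and unit variance.
  The resulting relative band powers — delta ≈ 7%, theta ≈ 6%,
  alpha ≈ 78% — describe an alpha-dominant awake, eyes-closed record.
* **Blinks**: smooth positive squared-half-sine pulses (gamma-shaped
  pulses behind a flag), width 0.35 s, at jittered-regular times with mean
  interval 5 s (Poisson timing optional), peak amplitude 8 in units of EEG
  standard deviation — frontal blink deflections are several-fold the
  background RMS. Pulse energy sits below 12 Hz.
* **Mixing** is exact by construction (s = q + p·k), and every generated
  object is deterministic per seed; `make_benchmark` records all per-trial
  seeds in a JSON manifest.

What the generator does *not* emulate: non-stationary alpha bursting,
electrode drift and cable artifacts, muscle (EMG) contamination, saccadic
eye movements, inter-subject spectral variability, and blink waveform
asymmetry. Passing tests therefore demonstrate the mechanism — correct
decomposition, selection and band removal under realistic spectra — not
clinical-grade performance on any particular recording system.

## Problem sizes in the tests

The randomized decomposition sweep uses 200 draws with t ∈ [100, 5000]
and R ∈ [4, 64]; the recovery benchmark uses 50 mixtures per mixing
constant (200 cleaning runs), chosen to make medians stable across seeds.
The whole suite completes in well under a minute.

## Known limitations

* Blink energy between ~3.9 Hz and the top of the first CiSSA band stays
  in the clean signal (it falls into DWT detail bands); conversely, the
  genuine sub-3.9 Hz EEG carried by flagged components is removed. The
  method trades these errors off by design; at fs = 250 Hz and R = 18
  both spillovers are small for typical blink widths (~0.3–0.4 s).
* Thresholding assumes at least one non-blink component for the score
  statistics to be meaningful; a segment that is wall-to-wall artifact
  will be under-cleaned.
* The 16-bit EDF writer stores one data record per file, which is exact
  for the segment lengths used here but makes very long records
  unwieldy; the text format is lossless and preferred for intermediate
  results.
* Single-channel by construction: no use of cross-channel redundancy, no
  joint/multichannel SSA, no streaming operation.
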