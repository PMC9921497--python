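# cissadwt

Automated removal of ocular (eye-blink / EOG) artifacts from
**single-channel EEG**, for researchers working with portable or few-channel
recordings where ICA-style multichannel decompositions are unavailable.

Eye blinks are high-amplitude, low-frequency (< ~12 Hz) deflections that
contaminate frontal EEG roughly every five seconds. This package removes
them in four linear stages:

1. **Circulant singular spectrum analysis (CiSSA).** The signal is embedded
   into an R×S Hankel trajectory matrix; the second-moment matrix is
   approximated by a circulant matrix built from sample autocovariances,
   M̂ₙ = ((R−n)/R)·γ̂ₙ + (n/R)·γ̂₍R₋ₙ₎. Its eigenvectors are the Fourier
   basis, so eigenvector *b* is tied to frequency (b−1)/R cycles/sample.
   Grouping conjugate pairs {b, R+2−b} and diagonal-averaging yields
   frequency-ordered components ("IMFs") that sum exactly to the input. At
   the tuned window R = 18 this gives 10 components in bands of fs/18 Hz.
2. **Kurtosis/energy selection.** Blink-carrying components are sparse and
   dominant, so they score high on both kurtosis K = m₄/m₂² and energy
   E = Σs². Components exceeding both thresholds (default: mean + 1 std
   across components) form the EOG stack EZ.
3. **4-level db4 DWT.** EZ is split by a Mallat cascade; the level-4
   approximation (≈ 0–fs/32 Hz, i.e. 0–3.9 Hz at 250 Hz) carries the blink
   and is zeroed; the detail bands are genuine EEG and are kept.
4. **Reconstruction.** Clean EEG q̂ = (unflagged components) + (EZ details);
   artifact estimate k̂ = (EZ approximation). By linearity, q̂ + k̂ equals
   the input exactly.

Evaluation metrics (RRMSE, Pearson CC, SAR in dB, alpha-band spectral MAE)
and a synthetic contaminated-EEG generator (mixing model **s = q + p·k**
with mixing constant p) are included, so the whole method is testable
without any recordings.

## Worked example

```python
import numpy as np
from cissadwt import BlinkParams, CissaDWTCleaner, evaluate, gen_eeg, gen_eog, mix

q = gen_eeg(2500, 250.0, seed=7)                    # ground-truth EEG (10 s)
k = gen_eog(2500, 250.0, BlinkParams(seed=8))       # blink train
m = mix(q, k, 1.0)                                  # contaminated: s = q + k

cleaner = CissaDWTCleaner().fit(np.zeros(2500))     # R=18, db4, 4 levels
res = cleaner.clean_segment(m.s)

print(res.segments[0].flags)      # which of the 10 components are EOG
print(evaluate(m.s.values, res.clean.values, res.artifact.values,
               fs=250.0, k=m.k.values).to_dict())
```

prints (numbers from this exact run):

```
[ True False False False False False False False False False]
{'rrmse_percent': 30.85591034504019, 'cc': 0.9736610609090296,
 'sar_db': 6.416379794063802, 'mae_band_power': 0.007045137867271812,
 'band_hz': [8.0, 13.0], 'psd_method': 'welch-256-hann-50%'}
```

Only the lowest-frequency component (0–~7 Hz band, kurtosis 21.2 vs ~3 for
the rest) is flagged as blink-related. The artifact estimate correlates
0.974 with the true blink train; the alpha-band spectral error is near
zero, i.e. the 8–13 Hz rhythm survives cleaning; and
`res.clean.values + res.artifact.values` reproduces the input to ~4e-15.

The same pipeline is available from the shell:

```sh
cissadwt simulate --out-dir corpus --n-trials 1 --seed 3
cissadwt clean corpus/trial000_p1_s.csv --fs 250 \
    --out-clean q.csv --out-artifact k.csv --out-diagnostics diag.json
cissadwt metrics -s corpus/trial000_p1_s.csv -q q.csv -k k.csv \
    --artifact-truth corpus/trial000_p1_k.csv --fs 250
```

`cissadwt decompose` dumps the raw components and their scores; EDF input
is accepted anywhere a file path is (`--channel` selects by label).

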