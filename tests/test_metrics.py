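"""Evaluation metrics: identities, hand values, brute-force equivalence."""

import numpy as np
import pytest

from cissadwt.core import ParameterError, UndefinedMetricError
from cissadwt.metrics import cc, evaluate, mae_band, rrmse, sar, sar_real
from cissadwt.synthetic import gen_eeg


class TestRRMSE:
    def test_identities(self, rng):
        k = rng.standard_normal(500)
        assert rrmse(k, k) == 0.0
        assert rrmse(k, np.zeros(500)) == pytest.approx(100.0)

    def test_hand_example(self):
        # diff = (0, 2): RMS diff = sqrt(2), RMS k = sqrt(2.5) -> 89.443%
        assert rrmse([1.0, 2.0], [1.0, 0.0]) == pytest.approx(
            np.sqrt(2.0 / 2.5) * 100.0, abs=1e-9
        )

    def test_monotone_in_error_scale(self, rng):
        k = rng.standard_normal(300)
        e = rng.standard_normal(300)
        vals = [rrmse(k, k + c * e) for c in [0.0, 0.1, 0.5, 1.0, 2.0]]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_zero_energy_truth_errors(self):
        with pytest.raises(UndefinedMetricError):
            rrmse(np.zeros(10), np.ones(10))


class TestCC:
    def test_identities(self, rng):
        k = rng.standard_normal(100)
        assert cc(k, k) == pytest.approx(1.0)
        assert cc(k, -k) == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        assert cc([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.98198051)

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedMetricError):
            cc(np.ones(10), np.arange(10.0))


class TestSAR:
    def test_log_ratio_values(self, rng):
        k = rng.standard_normal(10_000)
        e = rng.standard_normal(10_000)
        e *= k.std() / e.std()
        assert sar(k, k + e) == pytest.approx(0.0, abs=1e-9)
        assert sar(k, k + e / 10.0) == pytest.approx(10.0, abs=1e-9)

    def test_perfect_estimate_sentinel(self, rng):
        k = rng.standard_normal(50)
        assert sar(k, k) == np.inf

    def test_real_data_convention(self, rng):
        s = rng.standard_normal(2000)
        q_hat = s - 0.1 * rng.standard_normal(2000)
        direct = 10 * np.log10(np.std(s) / np.std(q_hat - s))
        assert sar_real(s, q_hat) == pytest.approx(direct, abs=1e-12)


class TestMAEBand:
    def test_identical_signals_give_zero(self):
        s = gen_eeg(2500, 250.0, seed=0).values
        assert mae_band(s, s, fs=250.0) == 0.0

    def test_low_frequency_removal_spares_alpha(self):
        fs, t = 250.0, 2500
        n = np.arange(t) / fs
        eeg = gen_eeg(t, fs, seed=1).values
        drift = 3.0 * np.sin(2 * np.pi * 2.0 * n)
        alpha = mae_band(eeg + drift, eeg, fs=fs, band=(8.0, 13.0))
        full = mae_band(eeg + drift, eeg, fs=fs, band=(0.5, 124.0))
        assert alpha < 0.01 * full

    def test_quadratic_in_amplitude(self):
        fs = 250.0
        s = gen_eeg(2500, fs, seed=2).values
        q = gen_eeg(2500, fs, seed=3).values
        assert mae_band(2 * s, 2 * q, fs=fs) == pytest.approx(
            4 * mae_band(s, q, fs=fs), rel=1e-9
        )

    def test_band_outside_nyquist_rejected(self):
        s = gen_eeg(2500, 250.0, seed=0).values
        with pytest.raises(ParameterError):
            mae_band(s, s, fs=250.0, band=(8.0, 200.0))


class TestBruteForceEquivalence:
    def test_all_metrics_match_one_liners(self, rng):
        """Independent one-line reimplementation oracle for each metric."""
        for _ in range(10):
            k = rng.standard_normal(400)
            kh = k + 0.3 * rng.standard_normal(400)
            assert rrmse(k, kh) == pytest.approx(
                np.sqrt(np.mean((k - kh) ** 2)) / np.sqrt(np.mean(k**2)) * 100,
                abs=1e-10,
            )
            assert cc(k, kh) == pytest.approx(
                np.cov(k, kh)[0, 1] / (k.std(ddof=1) * kh.std(ddof=1)), abs=1e-10
            )
            assert sar(k, kh) == pytest.approx(
                10 * np.log10(k.std() / (kh - k).std()), abs=1e-10
            )
            import scipy.signal

            f, ps = scipy.signal.welch(k, fs=250.0, window="hann", nperseg=256,
                                       noverlap=128)
            _, pq = scipy.signal.welch(kh, fs=250.0, window="hann", nperseg=256,
                                       noverlap=128)
            sel = (f >= 8.0) & (f <= 13.0)
            assert mae_band(k, kh, fs=250.0) == pytest.approx(
                np.mean(np.abs(ps[sel] - pq[sel])), abs=1e-10
            )


class TestEvaluate:
    def test_ground_truth_and_real_modes(self, rng):
        s = gen_eeg(2500, 250.0, seed=4).values
        q_hat = s * 0.9
        k = rng.standard_normal(2500)
        with_truth = evaluate(s, q_hat, k * 0.95, fs=250.0, k=k)
        assert with_truth.rrmse is not None and with_truth.cc is not None
        real = evaluate(s, q_hat, s - q_hat, fs=250.0)
        assert real.rrmse is None and real.cc is None
        assert real.sar == pytest.approx(sar_real(s, q_hat))
        assert set(real.to_dict()) == {
            "rrmse_percent", "cc", "sar_db", "mae_band_power", "band_hz",
            "psd_method",
        }
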