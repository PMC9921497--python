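"""CiSSA decomposition: embedding, circulant spectrum, grouping, hankelization."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st

from cissadwt.cissa import (
    CiSSA,
    circulant_eigens,
    circulant_first_row,
    cissa,
    embed,
    group_projectors,
    hankelize,
    n_groups,
)
from cissadwt.core import DegenerateSignalWarning, ParameterError


class TestEmbed:
    def test_small_example(self):
        A = embed(np.array([1.0, 2, 3, 4, 5]), R=2)
        assert np.array_equal(A, [[1, 2, 3, 4], [2, 3, 4, 5]])

    def test_constant_series_fills_matrix(self):
        A = embed(np.full(10, 3.25), R=4)
        assert A.shape == (4, 7)
        assert np.all(A == 3.25)

    def test_hankel_property_exhaustive(self, rng):
        x = rng.standard_normal(2500)
        A = embed(x, R=18)
        assert A.shape == (18, 2483)
        for k in range(18 + 2483 - 1):
            i = np.arange(max(0, k - 2482), min(18, k + 1))
            vals = A[i, k - i]
            assert np.all(vals == vals[0])

    @pytest.mark.parametrize("R", [1, 0, 100, 2500])
    def test_window_out_of_range_names_parameters(self, R, rng):
        with pytest.raises(ParameterError, match=rf"R={R}.*t="):
            embed(rng.standard_normal(100 if R < 2500 else 2500), R)


class TestCirculantFirstRow:
    def test_constant_series_is_zero_row_with_warning(self):
        with pytest.warns(DegenerateSignalWarning):
            row = circulant_first_row(np.full(50, 7.0), R=6)
        assert np.array_equal(row, np.zeros(6))

    def test_lag_zero_term_is_biased_variance(self, rng):
        x = rng.standard_normal(400)
        row = circulant_first_row(x, R=10)
        assert row[0] == pytest.approx(np.mean((x - x.mean()) ** 2), rel=1e-12)

    def test_matches_brute_force_autocovariance(self):
        x = np.tile([1.0, -1.0], 50)
        t, R = x.size, 4
        c = x - x.mean()
        gamma = [sum(c[i] * c[i + m] for i in range(t - m)) / t for m in range(R + 1)]
        expected = [
            ((R - n) / R) * gamma[n] + (n / R) * gamma[R - n] for n in range(R)
        ]
        row = circulant_first_row(x, R)
        np.testing.assert_allclose(row, expected, atol=1e-12)


class TestCirculantEigens:
    def test_scaled_identity_circulant(self):
        spec = circulant_eigens([4.5, 0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(spec.eigenvalues, 4.5)

    @pytest.mark.parametrize("R", range(2, 33))
    def test_matches_dense_eigendecomposition(self, R, rng):
        """Fourier-formula eigenvalues equal those of the explicit matrix."""
        row = circulant_first_row(rng.standard_normal(200), R)
        spec = circulant_eigens(row)
        dense = scipy.linalg.circulant(row)
        oracle = np.linalg.eigvalsh((dense + dense.T) / 2)
        np.testing.assert_allclose(
            np.sort(spec.eigenvalues), np.sort(oracle), atol=1e-9
        )
        # eigenpairs actually satisfy C v = mu v
        for b in range(R):
            v = spec.eigenvectors[:, b]
            np.testing.assert_allclose(
                dense @ v, spec.eigenvalues[b] * v, atol=1e-9 * max(1, abs(row[0]))
            )

    def test_psd_symmetry_and_conjugate_pairing(self, rng):
        row = circulant_first_row(rng.standard_normal(300), 9)
        spec = circulant_eigens(row)
        for b in range(2, 10):
            partner = 9 + 2 - b
            assert spec.eigenvalues[b - 1] == pytest.approx(
                spec.eigenvalues[partner - 1], abs=1e-10
            )
            np.testing.assert_allclose(
                spec.eigenvectors[:, b - 1],
                spec.eigenvectors[:, partner - 1].conj(),
                atol=1e-12,
            )

    def test_unit_norm_eigenvectors(self, rng):
        spec = circulant_eigens(circulant_first_row(rng.standard_normal(100), 12))
        np.testing.assert_allclose(
            np.linalg.norm(spec.eigenvectors, axis=0), 1.0, atol=1e-12
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ParameterError):
            circulant_eigens([1.0, np.nan, 0.0])


class TestGroupProjectors:
    def test_r18_gives_ten_documented_groups(self, rng):
        spec = circulant_eigens(circulant_first_row(rng.standard_normal(200), 18))
        groups = group_projectors(spec)
        assert [g for g, _ in groups] == [
            (1,), (2, 18), (3, 17), (4, 16), (5, 15),
            (6, 14), (7, 13), (8, 12), (9, 11), (10,),
        ]

    @pytest.mark.parametrize("R", [5, 6, 18, 19])
    def test_projector_algebra(self, R, rng):
        """Symmetric, idempotent, mutually orthogonal, complete."""
        spec = circulant_eigens(circulant_first_row(rng.standard_normal(300), R))
        groups = group_projectors(spec)
        total = np.zeros((R, R))
        for i, (_, P) in enumerate(groups):
            np.testing.assert_allclose(P, P.T, atol=1e-9)
            np.testing.assert_allclose(P @ P, P, atol=1e-9)
            for _, Q in groups[i + 1 :]:
                np.testing.assert_allclose(P @ Q, 0.0, atol=1e-9)
            total += P
        np.testing.assert_allclose(total, np.eye(R), atol=1e-9)

    def test_odd_window_projector_ranks(self, rng):
        spec = circulant_eigens(circulant_first_row(rng.standard_normal(100), 5))
        groups = group_projectors(spec)
        assert [g for g, _ in groups] == [(1,), (2, 5), (3, 4)]
        ranks = [int(round(np.trace(P))) for _, P in groups]
        assert ranks == [1, 2, 2]
        for _, P in groups:
            eigs = np.linalg.eigvalsh(P)
            assert np.sum(eigs > 0.5) == int(round(np.trace(P)))


class TestHankelize:
    def test_hand_computed_means(self):
        np.testing.assert_allclose(hankelize([[1.0, 2.0], [3.0, 4.0]]), [1, 2.5, 4])

    def test_fixed_point_on_hankel_matrix(self, rng):
        y = rng.standard_normal(40)
        np.testing.assert_allclose(hankelize(embed(y, 7)), y, atol=1e-12)

    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=1, max_value=6),
        st.floats(-5, 5),
        st.floats(-5, 5),
    )
    def test_linearity(self, r, s, a, b):
        rng = np.random.default_rng(7)
        M1, M2 = rng.standard_normal((2, r, s))
        np.testing.assert_allclose(
            hankelize(a * M1 + b * M2),
            a * hankelize(M1) + b * hankelize(M2),
            atol=1e-9,
        )


class TestCissa:
    def test_ten_components_at_tuned_window(self, rng):
        cs = cissa(rng.standard_normal(2500), R=18, fs=250.0)
        assert cs.n_components == 10

    def test_additive_reconstruction_randomized(self, rng):
        """Components sum back to the input over varied (t, R)."""
        for _ in range(200):
            t = int(rng.integers(100, 5001))
            R = int(rng.integers(4, min(65, t)))
            x = rng.standard_normal(t)
            cs = cissa(x, R=R)
            err = np.abs(cs.reconstruct() - x).max() / np.abs(x).max()
            assert err < 1e-8

    @pytest.mark.parametrize("R", range(2, 41))
    def test_group_count_and_frequency_ordering(self, R, rng):
        t = max(100, 2 * R)
        cs = cissa(rng.standard_normal(t), R=R, fs=250.0)
        assert cs.n_components == n_groups(R)
        assert cs.center_frequencies[0] == 0.0
        assert np.all(np.diff(cs.center_frequencies) > 0)

    @pytest.mark.parametrize("b", [2, 5, 9])
    def test_tone_isolation(self, b):
        """A sinusoid at a group frequency lands >= 99% in that group."""
        R, fs, t = 18, 250.0, 2500
        f = (b - 1) / R * fs
        x = np.sin(2 * np.pi * f * np.arange(t) / fs)
        cs = cissa(x, R=R, fs=fs)
        energies = np.sum(cs.components**2, axis=1)
        assert energies[b - 1] / energies.sum() >= 0.99

    def test_constant_series_goes_to_zero_frequency_group(self):
        with pytest.warns(DegenerateSignalWarning):
            cs = cissa(np.full(200, 2.5), R=8)
        np.testing.assert_allclose(cs.components[0], 2.5, atol=1e-12)
        np.testing.assert_allclose(cs.components[1:], 0.0, atol=1e-12)

    def test_estimator_interface(self, rng):
        est = CiSSA(window=12, fs=100.0)
        assert est.get_params() == {"window": 12, "fs": 100.0}
        comps = est.fit(rng.standard_normal(500)).components_
        assert comps.shape == (7, 500)
        clone_params = CiSSA().set_params(**est.get_params())
        assert clone_params.window == 12
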