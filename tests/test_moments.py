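"""Moment engine: oracles, orthogonality and invertibility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from icrotok import (
    MOMENT_ORDER,
    central_moments,
    hahn_basis,
    hahn_inverse,
    hahn_moments,
    hahn_polynomial,
    hahn_transform,
    moment_block,
    raw_moments,
    to_square_matrix,
)


def brute_raw(P, r, s):
    m = P.shape[0]
    return sum(
        (a + 1) ** r * (b + 1) ** s * P[a, b]
        for a in range(m) for b in range(m)
    )


def brute_central(P, r, s):
    m = P.shape[0]
    m00 = P.sum()
    xbar = brute_raw(P, 1, 0) / m00
    ybar = brute_raw(P, 0, 1) / m00
    return sum(
        (a + 1 - xbar) ** r * (b + 1 - ybar) ** s * P[a, b]
        for a in range(m) for b in range(m)
    )


int_matrices = arrays(
    np.int64, (5, 5), elements=st.integers(min_value=0, max_value=50)
)


class TestSquareLayout:
    def test_41_mer_fits_7x7_with_8_zeros(self):
        P = to_square_matrix(np.arange(1, 42))
        assert P.shape == (7, 7)
        assert np.count_nonzero(P == 0) == 8
        assert P[0, 0] == 1 and P[5, 5] == 41  # row-major fill

    def test_exact_square(self):
        assert np.array_equal(
            to_square_matrix([1, 2, 3, 4]), [[1, 2], [3, 4]]
        )

    def test_single_value(self):
        assert to_square_matrix([5]).shape == (1, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            to_square_matrix([])


class TestRawMoments:
    def test_m00_is_matrix_sum(self):
        assert raw_moments(np.array([[1, 2], [3, 4]]))[(0, 0)] == 10

    def test_m10_worked_example(self):
        assert raw_moments(np.array([[1, 2], [3, 4]]))[(1, 0)] == 17

    def test_zero_matrix(self):
        assert np.all(raw_moments(np.zeros((3, 3))).coefficients == 0)

    @given(int_matrices)
    def test_matches_double_loop_oracle_exactly(self, P):
        got = raw_moments(P.astype(float))
        for r, s in MOMENT_ORDER:
            assert got[(r, s)] == brute_raw(P, r, s)


class TestCentralMoments:
    def test_centering_identities(self, rng):
        P = rng.random((6, 6)) + 0.1
        got = central_moments(P)
        assert got[(0, 0)] == pytest.approx(P.sum())
        assert got[(1, 0)] == pytest.approx(0, abs=1e-10)
        assert got[(0, 1)] == pytest.approx(0, abs=1e-10)

    def test_i20_worked_example(self):
        assert central_moments(np.array([[1.0, 2.0], [3.0, 4.0]]))[(2, 0)] == (
            pytest.approx(2.1)
        )

    def test_translation_invariance(self, rng):
        block = rng.random((3, 3)) + 0.5
        P1, P2 = np.zeros((9, 9)), np.zeros((9, 9))
        P1[0:3, 0:3] = block
        P2[4:7, 5:8] = block
        np.testing.assert_allclose(
            central_moments(P1).coefficients,
            central_moments(P2).coefficients,
            atol=1e-9,
        )

    def test_zero_mass_defined_as_zero(self):
        assert np.all(central_moments(np.zeros((4, 4))).coefficients == 0)

    @given(int_matrices.filter(lambda P: P.sum() > 0))
    def test_matches_double_loop_oracle(self, P):
        got = central_moments(P.astype(float))
        for r, s in MOMENT_ORDER:
            assert got[(r, s)] == pytest.approx(
                brute_central(P, r, s), rel=1e-9, abs=1e-9
            )


class TestHahnPolynomial:
    @pytest.mark.parametrize("M,u,z", [(5, 0.0, 0.0), (9, 2.0, 3.0), (7, 0.5, 1.5)])
    def test_zeroth_order_is_one(self, M, u, z):
        for r in range(M):
            assert float(hahn_polynomial(0, r, M, u, z)) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hahn_polynomial(7, 0, 7)
        with pytest.raises(ValueError):
            hahn_polynomial(0, 9, 7)
        with pytest.raises(ValueError):
            hahn_polynomial(1, 1, 7, u=-1.5)

    @pytest.mark.parametrize("M,u,z", [(8, 0.0, 0.0), (8, 1.0, 2.0), (6, 0.5, 0.5)])
    def test_discrete_orthogonality_by_direct_summation(self, M, u, z):
        from icrotok.moments import _hahn_weight

        for n in range(M):
            for k in range(n):
                acc = sum(
                    float(_hahn_weight(r, M, u, z))
                    * float(hahn_polynomial(n, r, M, u, z))
                    * float(hahn_polynomial(k, r, M, u, z))
                    for r in range(M)
                )
                norm = sum(
                    float(_hahn_weight(r, M, u, z))
                    * float(hahn_polynomial(n, r, M, u, z)) ** 2
                    for r in range(M)
                )
                assert abs(acc) / norm < 1e-9

    def test_uz_zero_reduces_to_discrete_chebyshev(self):
        # oracle: QR of the Vandermonde matrix on {0..M-1} gives the
        # (sign-ambiguous) orthonormal polynomial basis for uniform weight
        M = 9
        V = np.vander(np.arange(M, dtype=float), M, increasing=True)
        Q, _ = np.linalg.qr(V)
        B = hahn_basis(M)
        for n in range(M):
            err = min(
                np.abs(B[n] - Q[:, n]).max(), np.abs(B[n] + Q[:, n]).max()
            )
            assert err < 1e-10


class TestHahnMoments:
    @pytest.mark.parametrize("m", range(4, 17))
    def test_basis_gram_is_identity(self, m):
        B = hahn_basis(m)
        assert np.abs(B @ B.T - np.eye(m)).max() < 1e-10

    def test_full_order_round_trip(self, rng):
        for _ in range(5):
            P = rng.normal(size=(7, 7))
            assert np.abs(P - hahn_inverse(hahn_transform(P))).max() < 1e-8

    def test_zero_matrix(self):
        assert np.all(hahn_moments(np.zeros((5, 5))).coefficients == 0)

    def test_too_small_support_rejected(self):
        with pytest.raises(ValueError):
            hahn_moments(np.ones((3, 3)))

    def test_h00_constant_matrix_vs_direct_summation(self):
        m, c = 6, 2.5
        P = np.full((m, m), c)
        B = hahn_basis(m)
        direct = sum(
            P[a, b] * B[0, b] * B[0, a] for a in range(m) for b in range(m)
        )
        assert hahn_moments(P)[(0, 0)] == pytest.approx(direct)


class TestMomentBlock:
    def test_length_and_ordering(self, rng):
        P = rng.random((7, 7))
        block = moment_block(P)
        assert block.shape == (30,)
        np.testing.assert_array_equal(block[:10], raw_moments(P).coefficients)
        np.testing.assert_array_equal(
            block[10:20], central_moments(P).coefficients
        )
        np.testing.assert_array_equal(
            block[20:], hahn_moments(P).coefficients
        )

    def test_zero_matrix_gives_30_zeros(self):
        assert np.all(moment_block(np.zeros((5, 5))) == 0)
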