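"""Packed-symmetric storage, batched kernels, and quantization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikerls.linalg import (BatchedP, PackedSymmetric, dequantize, get_precision,
                             packed_index, packed_length, quantize)


def dense_from_packed(pdata, dim, spec="f64"):
    """Independent dense oracle: unpack by explicit index arithmetic."""
    vals = dequantize(pdata, get_precision(spec))
    out = np.empty((dim, dim))
    for j in range(dim):
        for i in range(j + 1):
            out[i, j] = out[j, i] = vals[i + j * (j + 1) // 2]
    return out


class TestPackedIndex:
    @pytest.mark.parametrize("i,j,L,expected", [
        (0, 0, 4, 0),
        (1, 2, 4, 4),          # closed form i + j(j+1)/2
        (2, 1, 4, 4),          # symmetry
        (3, 3, 4, 9),
    ])
    def test_examples(self, i, j, L, expected):
        assert packed_index(i, j, L) == expected

    @given(st.integers(1, 24))
    @settings(max_examples=30, derandomize=True)
    def test_bijection_onto_triangle(self, L):
        offsets = {packed_index(i, j, L) for j in range(L) for i in range(j + 1)}
        assert offsets == set(range(packed_length(L)))

    @given(st.integers(1, 24), st.data())
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_in_arguments(self, L, data):
        i = data.draw(st.integers(0, L - 1))
        j = data.draw(st.integers(0, L - 1))
        assert packed_index(i, j, L) == packed_index(j, i, L)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            packed_index(0, 4, 4)
        with pytest.raises(IndexError):
            packed_index(-1, 0, 4)


class TestQuantization:
    def test_scale_values(self):
        assert get_precision("i16").scale == 16384
        assert get_precision("i12_in_i16").scale == 1024
        assert get_precision("i8").scale == 64

    @pytest.mark.parametrize("value,code,expected", [
        (1.0, "i16", 16384),
        (-1.0, "i8", -64),
        (2.0, "i16", 32767),           # saturates, never wraps
        (-4.0, "i8", -128),
        (1.5, "i12_in_i16", 1536),
    ])
    def test_examples(self, value, code, expected):
        assert quantize(value, get_precision(code)) == expected

    @pytest.mark.parametrize("code", ["i16", "i12_in_i16", "i8"])
    def test_roundtrip_error_bound(self, code):
        spec = get_precision(code)
        in_range = spec.qmax / spec.scale
        grid = np.linspace(-in_range, in_range, 4001)
        err = np.abs(dequantize(quantize(grid, spec), spec) - grid)
        assert err.max() <= 0.5 / spec.scale + 1e-12

    def test_i12_never_exceeds_12bit_range_for_typical_p(self):
        spec = get_precision("i12_in_i16")
        grid = np.linspace(-1.999, 1.999, 2001)
        stored = quantize(grid, spec)
        assert np.abs(stored).max() <= 2047

    def test_saturation_engages_at_boundary(self):
        spec = get_precision("i8")
        edge = spec.qmax / spec.scale
        assert quantize(edge, spec) == spec.qmax
        assert quantize(edge + 1.0, spec) == spec.qmax
        assert quantize(-edge - 1.0, spec) == spec.qmin


class TestPackedSymmetric:
    def test_dense_roundtrip_is_identity(self, rng):
        m = rng.normal(size=(6, 6))
        m = m + m.T
        ps = PackedSymmetric.from_dense(m)
        assert np.allclose(ps.to_dense(), m)
        assert ps.data.shape == (packed_length(6),)

    def test_unpacked_matrix_is_symmetric(self, rng):
        ps = PackedSymmetric(5, rng.normal(size=packed_length(5)))
        d = ps.to_dense()
        assert np.array_equal(d, d.T)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            PackedSymmetric(4, np.zeros(9))

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError):
            PackedSymmetric.from_dense(rng.normal(size=(4, 4)))


class TestBatchedKernels:
    @pytest.mark.parametrize("precision,tol", [("f64", 1e-12), ("f32", 1e-6)])
    def test_matvec_matches_dense_oracle(self, precision, tol, rng):
        n, L = 16, 32
        P = BatchedP(n, L, precision,
                     data=rng.normal(size=(n, packed_length(L))).astype(
                         get_precision(precision).dtype))
        x = rng.normal(size=(n, L))
        y = P.matvec(x, alpha=1.3, beta=0.0)
        for i in range(n):
            ref = 1.3 * dense_from_packed(np.asarray(P.data[i], dtype=np.float64), L) @ x[i]
            assert np.linalg.norm(y[i] - ref) <= tol * max(np.linalg.norm(ref), 1.0)

    @pytest.mark.parametrize("precision,tol", [("f64", 1e-12), ("f32", 1e-6)])
    def test_rank1_matches_dense_oracle(self, precision, tol, rng):
        n, L = 16, 32
        spec = get_precision(precision)
        data = rng.normal(size=(n, packed_length(L))).astype(spec.dtype)
        P = BatchedP(n, L, precision, data=data.copy())
        x = rng.normal(size=(n, L))
        alpha = rng.normal(size=n)
        P.rank1_update(alpha, x)
        for i in range(n):
            ref = (dense_from_packed(data[i].astype(np.float64), L)
                   + alpha[i] * np.outer(x[i], x[i]))
            got = P.to_dense(i)
            assert np.linalg.norm(got - ref) <= tol * np.linalg.norm(ref)

    def test_identity_matvec_returns_input(self, rng):
        P = BatchedP.scaled_identity(4, 8, 1.0)
        x = rng.normal(size=(4, 8))
        assert np.allclose(P.matvec(x), x)

    def test_alpha_zero_beta_one_leaves_y(self, rng):
        P = BatchedP(3, 5, data=rng.normal(size=(3, packed_length(5))))
        y = rng.normal(size=(3, 5))
        y0 = y.copy()
        P.matvec(rng.normal(size=(3, 5)), alpha=0.0, beta=1.0, out=y)
        assert np.array_equal(y, y0)

    def test_rank1_alpha_zero_is_noop(self, rng):
        P = BatchedP(3, 5, data=rng.normal(size=(3, packed_length(5))))
        before = P.data.copy()
        P.rank1_update(np.zeros(3), rng.normal(size=(3, 5)))
        assert np.array_equal(P.data, before)

    def test_rank1_on_zero_touches_single_element(self):
        P = BatchedP(1, 4)
        x = np.zeros((1, 4))
        x[0, 0] = 1.0
        P.rank1_update(np.ones(1), x)
        expected = np.zeros(packed_length(4))
        expected[packed_index(0, 0, 4)] = 1.0
        assert np.array_equal(P.data[0], expected)

    def test_integer_matvec_dequantizes_during_accumulation(self, rng):
        n, L = 4, 6
        P = BatchedP.scaled_identity(n, L, 1.5, "i16")
        x = rng.normal(size=(n, L))
        assert np.allclose(P.matvec(x), 1.5 * x, atol=1e-3)

    def test_integer_rank1_requantizes_with_saturation(self):
        P = BatchedP.scaled_identity(1, 2, 1.9, "i16")   # near the ceiling
        x = np.ones((1, 2))
        P.rank1_update(np.full(1, 10.0), x)              # would exceed +2
        assert np.all(P.data <= 32767)
        assert P.to_dense(0).max() <= 32767 / 16384

    def test_dim_mismatch_rejected(self, rng):
        P = BatchedP(3, 5)
        with pytest.raises(ValueError):
            P.matvec(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            P.rank1_update(np.ones(3), rng.normal(size=(2, 5)))


class TestMemoryFootprint:
    @pytest.mark.parametrize("code,bytes_per", [("f64", 8), ("f32", 4),
                                                ("i16", 2), ("i8", 1)])
    def test_packed_footprint_is_half_dense(self, code, bytes_per):
        n, L = 7, 12
        P = BatchedP(n, L, code)
        assert P.nbytes == n * packed_length(L) * bytes_per
        assert P.nbytes < n * L * L * bytes_per * 0.6

    def test_scaled_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            BatchedP.scaled_identity(2, 4, 2.5, "i16")   # 2.5 > 32767/16384
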