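"""SISO Volterra model: regressors, least-squares identification, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misovolterra import (
    Signal,
    VolterraKernels,
    build_regressors,
    fit_siso,
    kernel_index,
    load_kernels,
    n_parameters,
    predict,
    save_kernels,
    spectrum,
)


def _sig(arr, fs=1.0):
    return Signal(np.asarray(arr, dtype=float), fs)


class TestRegressors:
    def test_parameter_count_formula(self):
        # 1 + M + M(M+1)/2 + M(M+1)(M+2)/6
        assert n_parameters(2, 3) == 1 + 2 + 3 + 4
        assert n_parameters(19, 3) == 1540

    def test_all_ones_input_gives_all_ones_regressors(self):
        X = build_regressors(_sig(np.ones(10)), M=3, P=3)
        assert X.shape == (8, n_parameters(3, 3))
        np.testing.assert_array_equal(X, np.ones_like(X))

    def test_hand_enumerated_row(self):
        # x = [1, 2, 3], M=2, P=2; row n=1: {1, x(1), x(0), x(1)^2, x(1)x(0), x(0)^2}
        X = build_regressors(_sig([1.0, 2.0, 3.0]), M=2, P=2)
        np.testing.assert_array_equal(X[0], [1.0, 2.0, 1.0, 4.0, 2.0, 1.0])
        np.testing.assert_array_equal(X[1], [1.0, 3.0, 2.0, 9.0, 6.0, 4.0])

    def test_row_count_is_length_minus_memory_plus_one(self):
        X = build_regressors(_sig(np.arange(50.0)), M=7, P=1)
        assert X.shape[0] == 44

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="shorter than memory"):
            build_regressors(_sig([1.0, 2.0]), M=5, P=2)

    def test_column_order_is_sorted_lag_tuples(self):
        cols = kernel_index(2, 3)
        assert cols == [(), (0,), (1,), (0, 0), (0, 1), (1, 1),
                        (0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)]


class TestFitSiso:
    def test_recovers_known_random_kernels(self):
        rng = np.random.default_rng(42)
        M, P, L = 3, 3, 500
        x = _sig(rng.normal(size=L))
        true = VolterraKernels.unpack(rng.normal(size=n_parameters(M, P)), M, P)
        y = predict(true, x)
        est = fit_siso(x, y, M, P)
        np.testing.assert_allclose(est.pack(), true.pack(), rtol=0, atol=1e-8)

    def test_pure_gain_system(self):
        rng = np.random.default_rng(0)
        x = _sig(rng.normal(size=200))
        y = x.copy_with(2.0 * x.samples)
        est = fit_siso(x, y, M=3, P=3)
        np.testing.assert_allclose(est.h1, [2.0, 0.0, 0.0], atol=1e-9)
        assert abs(est.h0) < 1e-9
        np.testing.assert_allclose(est.h2, 0.0, atol=1e-9)
        np.testing.assert_allclose(est.h3, 0.0, atol=1e-9)

    def test_pointwise_square_system(self):
        rng = np.random.default_rng(1)
        x = _sig(rng.normal(size=200))
        y = x.copy_with(x.samples**2)
        est = fit_siso(x, y, M=2, P=2)
        idx = kernel_index(2, 2).index((0, 0))
        h = est.pack()
        assert h[idx] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(h, idx)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_all_zero_input_returns_output_mean_as_h0(self):
        x = _sig(np.zeros(50))
        y = _sig(np.full(50, 3.5))
        est = fit_siso(x, y, M=2, P=2)
        assert est.h0 == pytest.approx(3.5)
        assert est.residual_db < -100  # nothing left once the mean is removed

    def test_residual_orthogonal_to_regressor_columns(self, tone):
        # normal-equations optimality at the LS solution
        x, _ = tone
        rng = np.random.default_rng(7)
        y = x.copy_with(np.tanh(x.samples) + 0.1 * rng.normal(size=len(x)))
        M, P = 4, 3
        est = fit_siso(x, y, M, P)
        X = build_regressors(x, M, P)
        resid = y.samples[M - 1 :] - X @ est.pack()
        scale = np.linalg.norm(X, axis=0) * np.linalg.norm(resid) + 1e-300
        assert np.max(np.abs(X.T @ resid) / scale) < 1e-8

    def test_homogeneity_in_output_scale(self):
        rng = np.random.default_rng(3)
        x = _sig(rng.normal(size=120))
        y = x.copy_with(x.samples + 0.3 * x.samples**2)
        base = fit_siso(x, y, M=2, P=3).pack()
        scaled = fit_siso(x, y.copy_with(5.0 * y.samples), M=2, P=3).pack()
        np.testing.assert_allclose(scaled, 5.0 * base, rtol=1e-8, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        x = _sig(np.ones(10), fs=1.0)
        y = _sig(np.ones(10), fs=2.0)
        with pytest.raises(ValueError, match="share"):
            fit_siso(x, y, M=2)


class TestPredict:
    def test_constant_kernel_gives_constant_output(self):
        M = 3
        h = VolterraKernels(M=M, P=1, h0=4.2, h1=np.zeros(M))
        x = _sig(np.random.default_rng(0).normal(size=30))
        out = predict(h, x)
        np.testing.assert_array_equal(out.samples[: M - 1], 0.0)  # invalid rows
        np.testing.assert_allclose(out.samples[M - 1 :], 4.2)

    def test_spectral_closure_on_pure_tone(self, tone):
        # third-order polynomial of a tone lives on {0, f0, 2f0, 3f0} only
        x, f0 = tone
        rng = np.random.default_rng(11)
        M, P = 5, 3
        h = VolterraKernels.unpack(rng.normal(size=n_parameters(M, P)), M, P)
        out = predict(h, x)
        # whole carrier periods inside the valid region: samples 15..270
        seg = Signal(out.samples[15:270], x.fs)
        freqs, power = spectrum(seg)
        keep = np.zeros_like(power, dtype=bool)
        for f_c in (0.0, f0, 2 * f0, 3 * f0):
            keep |= np.abs(freqs - f_c) <= 1.5 * x.fs / len(seg)
        assert power[~keep].sum() / power.sum() < 1e-10

    def test_symmetric_tensor_expansion_preserves_the_map(self):
        rng = np.random.default_rng(5)
        M, P = 3, 3
        h = VolterraKernels.unpack(rng.normal(size=n_parameters(M, P)), M, P)
        x = rng.normal(size=40)
        sig = _sig(x)
        expected = predict(h, sig).samples
        h2f, h3f = h.to_symmetric(2), h.to_symmetric(3)
        # full permutation-redundant summation
        full = np.zeros(40)
        for n in range(M - 1, 40):
            lags = x[n - M + 1 : n + 1][::-1]
            full[n] = (
                h.h0
                + h.h1 @ lags
                + np.einsum("ij,i,j->", h2f, lags, lags)
                + np.einsum("ijk,i,j,k->", h3f, lags, lags, lags)
            )
        np.testing.assert_allclose(full[M - 1 :], expected[M - 1 :], rtol=1e-10, atol=1e-10)


class TestSerialization:
    def test_npz_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        h = VolterraKernels.unpack(rng.normal(size=n_parameters(4, 3)), 4, 3)
        path = tmp_path / "k.npz"
        save_kernels(h, path)
        back = load_kernels(path)
        np.testing.assert_array_equal(back.pack(), h.pack())
        assert (back.M, back.P) == (4, 3)

    def test_pack_unpack_roundtrip(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=n_parameters(3, 2))
        h = VolterraKernels.unpack(v, 3, 2)
        np.testing.assert_array_equal(h.pack(), v)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=1, max_value=5), st.integers(min_value=1, max_value=3))
def test_parameter_count_matches_column_enumeration(M, P):
    assert len(kernel_index(M, P)) == n_parameters(M, P)
    X = build_regressors(_sig(np.arange(1.0, 12.0)), M, P)
    assert X.shape[1] == n_parameters(M, P)
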