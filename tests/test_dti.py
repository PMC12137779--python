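"""Tensor model inversion, scalar invariants, and noise behavior."""

import numpy as np
import pandas as pd
import pytest

from cdti.dti import (
    design_matrix,
    fa,
    fit_tensor,
    interpolate_series,
    md,
    principal_direction,
    tensors_to_matrices,
)
from cdti.io_formats import DiffusionScheme, ImageSeries
from cdti.phantom import spread_directions


def _protocol_scheme(seed=0):
    dirs = spread_directions(12, seed=seed)
    b = np.concatenate([np.full(12, 50.0), np.full(12, 500.0)])
    return DiffusionScheme(b, np.vstack([dirs, dirs]))


def _series_from_signals(signals, shape=(4, 4)):
    """Constant-image series: one frame per measurement, all pixels equal."""
    n = len(signals)
    frames = np.tile(np.asarray(signals, float)[:, None, None], (1, *shape))
    meta = pd.DataFrame({
        "b_value": [50.0] * 12 + [500.0] * (n - 12),
        "direction_index": list(range(12)) + list(range(n - 12)),
        "average_index": 0,
        "acquisition_order": range(n),
    })
    return ImageSeries(frames, (1.4, 1.4), meta)


def _signals(D, scheme, s0=1.0):
    g = scheme.directions
    b = scheme.b_values / 1000.0
    return s0 * np.exp(-b * np.einsum("ij,jk,ik->i", g, D, g))


class TestFit:
    def test_noiseless_isotropic_recovery_exact(self):
        scheme = _protocol_scheme()
        D = np.diag([1.5, 1.5, 1.5])
        series = _series_from_signals(_signals(D, scheme, s0=100.0))
        tf = fit_tensor(series, scheme)
        np.testing.assert_allclose(tf.matrices[2, 2], D, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(tf.s0[2, 2], 100.0, rtol=1e-8)

    def test_noiseless_anisotropic_recovery_exact(self):
        scheme = _protocol_scheme()
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        D = q @ np.diag([2.0, 1.2, 1.0]) @ q.T
        series = _series_from_signals(_signals(D, scheme))
        tf = fit_tensor(series, scheme)
        np.testing.assert_allclose(tf.matrices[0, 0], D, rtol=1e-8, atol=1e-10)

    def test_all_zero_pixel_excluded(self):
        scheme = _protocol_scheme()
        series = _series_from_signals(_signals(np.diag([1.5, 1.5, 1.5]), scheme))
        series.frames[:, 1, 1] = 0.0
        tf = fit_tensor(series, scheme)
        assert not tf.mask[1, 1]
        assert np.isnan(tf.tensors[1, 1]).all()
        assert tf.mask[0, 0]

    def test_rank_deficient_scheme_rejected(self):
        b = np.full(12, 500.0)
        dirs = np.tile([[1.0, 0, 0], [0, 1.0, 0]], (6, 1))
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_tensor(
                _series_from_signals(np.ones(12)),
                DiffusionScheme(b, dirs),
            )

    def test_rician_noise_bias_bounds(self):
        """MD within 5% and FA within 0.03 (median over draws) at SNR 25
        with 8-average high-b measurements."""
        scheme = _protocol_scheme()
        rng = np.random.default_rng(7)
        lam = np.array([2.0, 1.2, 1.0])
        D = np.diag(lam)
        clean = _signals(D, scheme)
        n_avg = np.where(scheme.b_values == 500.0, 8, 1)
        sigma = clean[:12].mean() / 25.0
        mds, fas = [], []
        for _ in range(200):
            sig = np.empty_like(clean)
            for i, (s, na) in enumerate(zip(clean, n_avg)):
                draws = np.hypot(s + rng.normal(0, sigma, na), rng.normal(0, sigma, na))
                sig[i] = draws.mean()
            series = _series_from_signals(sig, shape=(1, 1))
            tf = fit_tensor(series, scheme)
            mds.append(md(tf.matrices[0, 0]))
            fas.append(fa(tf.matrices[0, 0]))
        md_true, fa_true = lam.mean(), fa(D)
        assert abs(np.median(mds) - md_true) / md_true < 0.05
        assert abs(np.median(fas) - fa_true) < 0.03

    def test_fa_noise_bias_grows_as_snr_falls(self):
        """Eigenvalue repulsion: the positive FA bias at SNR 10 must exceed
        the bias at SNR 40 (200 Rician draws each, fixed seeds)."""
        scheme = _protocol_scheme()
        lam = np.array([2.0, 1.2, 1.0])
        clean = _signals(np.diag(lam), scheme)
        fa_true = fa(np.diag(lam))

        def bias(snr, seed):
            rng = np.random.default_rng(seed)
            sigma = clean[:12].mean() / snr
            out = []
            for _ in range(200):
                sig = np.hypot(clean + rng.normal(0, sigma, clean.shape),
                               rng.normal(0, sigma, clean.shape))
                tf = fit_tensor(_series_from_signals(sig, shape=(1, 1)), scheme)
                out.append(fa(tf.matrices[0, 0]))
            return np.median(out) - fa_true

        assert bias(10, seed=11) > bias(40, seed=12)


class TestScalars:
    def test_md_closed_forms(self):
        assert md(np.diag([1.0, 1, 1])) == pytest.approx(1.0)
        assert md(np.diag([2.0, 1, 1])) == pytest.approx(4 / 3)

    def test_fa_closed_forms(self):
        assert fa(np.diag([1.0, 1, 1])) == pytest.approx(0.0, abs=1e-12)
        assert fa(np.diag([3.0, 0, 0])) == pytest.approx(1.0)
        assert fa(np.diag([2.0, 1, 1])) == pytest.approx(np.sqrt(1 / 6), abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        D = np.diag([2.0, 1.0, 1.0])
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            Dr = q @ D @ q.T
            assert md(Dr) == pytest.approx(4 / 3, abs=1e-10)
            assert fa(Dr) == pytest.approx(np.sqrt(1 / 6), abs=1e-10)

    def test_principal_direction_and_degeneracy(self):
        v = principal_direction(np.diag([2.0, 1.0, 1.0]))
        assert abs(v @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-12)
        assert np.isnan(principal_direction(np.eye(3))).all()

    def test_packed_matrix_expansion(self):
        packed = np.array([1.0, 2.0, 3.0, 0.1, 0.2, 0.3])
        m = tensors_to_matrices(packed)
        assert m[0, 1] == m[1, 0] == 0.1
        assert m[0, 2] == m[2, 0] == 0.2
        assert m[1, 2] == m[2, 1] == 0.3
        np.testing.assert_allclose(np.diag(m), [1, 2, 3])


class TestInterpolation:
    def test_grid_arithmetic_48_cols(self):
        meta = pd.DataFrame({
            "b_value": [50.0], "direction_index": [0],
            "average_index": [0], "acquisition_order": [0],
        })
        s = ImageSeries(np.zeros((1, 128, 48)), (2.7, 2.7), meta)
        out = interpolate_series(s, (1.4, 1.4))
        assert out.shape == (247, 93)

    def test_constant_preserved(self):
        meta = pd.DataFrame({
            "b_value": [50.0], "direction_index": [0],
            "average_index": [0], "acquisition_order": [0],
        })
        s = ImageSeries(np.full((1, 20, 20), 7.5), (2.7, 2.7), meta)
        out = interpolate_series(s, (1.4, 1.4))
        np.testing.assert_allclose(out.frames, 7.5, rtol=1e-12)

    def test_identity_when_target_equals_source(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame({
            "b_value": [50.0], "direction_index": [0],
            "average_index": [0], "acquisition_order": [0],
        })
        s = ImageSeries(rng.random((1, 10, 10)), (1.4, 1.4), meta)
        out = interpolate_series(s, (1.4, 1.4))
        np.testing.assert_array_equal(out.frames, s.frames)
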