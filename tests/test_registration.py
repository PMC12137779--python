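"""Contracts of the demons registration engine.

The independent oracle for accuracy is SimpleITK's diffeomorphic demons,
used on synthetic smooth-warp pairs with known ground truth (tests only).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdti.registration import (
    DisplacementFieldPair,
    RegistrationParams,
    compose,
    field_exp,
    inverse_consistency_error,
    jacobian_determinant,
    register_pair,
    warp,
)

from conftest import smooth_lv_image


def uniform_field(shape, dr=0.0, dc=0.0):
    f = np.zeros((2, *shape))
    f[0] = dr
    f[1] = dc
    return f


class TestWarpCompose:
    def test_zero_field_is_identity(self, lv_image):
        out = warp(lv_image, uniform_field(lv_image.shape))
        np.testing.assert_array_equal(out, lv_image)

    def test_pullback_convention_on_impulse(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = warp(img, uniform_field(img.shape, dc=2.0))
        # out(p) = img(p + 2 cols): the impulse appears 2 columns earlier
        assert out[2, 0] == 1.0 and out[2, 2] == 0.0

    def test_nearest_mode_preserves_binary(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((12, 12)) > 0.5).astype(float)
        out = warp(mask, uniform_field(mask.shape, dr=0.3, dc=-0.7), mode="nearest")
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_compose_with_zero_is_identity(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0, 0.5, (2, 10, 10))
        np.testing.assert_allclose(compose(uniform_field((10, 10)), g), g)

    def test_compose_adds_uniform_translations(self):
        f = uniform_field((20, 20), dr=1.0)
        g = uniform_field((20, 20), dr=2.0)
        out = compose(f, g)
        np.testing.assert_allclose(out[0][3:-3, 3:-3], 3.0)

    @settings(max_examples=20, deadline=None)
    @given(dr=st.floats(-2, 2), dc=st.floats(-2, 2))
    def test_exp_of_uniform_velocity_is_uniform_translation(self, dr, dc):
        d = field_exp(uniform_field((16, 16), dr, dc))
        np.testing.assert_allclose(d[0][4:-4, 4:-4], dr, atol=1e-9)
        np.testing.assert_allclose(d[1][4:-4, 4:-4], dc, atol=1e-9)


class TestInverseConsistencyError:
    def test_zero_fields(self):
        pair = DisplacementFieldPair(uniform_field((20, 20)), uniform_field((20, 20)))
        assert inverse_consistency_error(pair) == 0.0

    def test_exact_inverse_translations(self):
        pair = DisplacementFieldPair(
            uniform_field((32, 32), dr=3.0), uniform_field((32, 32), dr=-3.0)
        )
        assert inverse_consistency_error(pair) == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_translations(self):
        pair = DisplacementFieldPair(
            uniform_field((32, 32), dr=3.0), uniform_field((32, 32), dr=-2.0)
        )
        assert inverse_consistency_error(pair) == pytest.approx(1.0, abs=1e-12)


class TestRegisterPair:
    def test_identity_registration(self, lv_image):
        pair = register_pair(lv_image, lv_image)
        assert np.hypot(*pair.forward).mean() < 0.05

    def test_translation_recovery(self, lv_image, lv_mask):
        moving = warp(lv_image, uniform_field(lv_image.shape, dr=3.0))
        pair = register_pair(lv_image, moving)
        # moving(p) = fixed(p+3): aligning it back needs forward ~ -3 rows
        assert pair.forward[0][lv_mask].mean() == pytest.approx(-3.0, abs=0.5)
        assert inverse_consistency_error(pair) < 0.1

    def test_cross_contrast_zero_motion(self, still_phantom):
        _, series, truth = still_phantom
        b = series.b_values
        fixed = series.frames[np.argmax(b == 50.0)]
        moving = series.frames[np.argmax(b == 500.0)]
        pair = register_pair(fixed, moving)
        assert np.hypot(*pair.forward)[truth.geometry.mask].mean() < 0.5

    def test_symmetry_forward_vs_swapped_inverse(self, lv_image, lv_mask):
        moving = warp(lv_image, uniform_field(lv_image.shape, dr=2.0, dc=0.5))
        ab = register_pair(lv_image, moving)
        ba = register_pair(moving, lv_image)
        diff = np.hypot(ab.forward[0] - ba.inverse[0], ab.forward[1] - ba.inverse[1])
        assert diff[lv_mask].mean() < 0.25

    def test_determinism(self, lv_image):
        moving = warp(lv_image, uniform_field(lv_image.shape, dr=1.5))
        a = register_pair(lv_image, moving)
        b = register_pair(lv_image, moving)
        np.testing.assert_array_equal(a.forward, b.forward)
        np.testing.assert_array_equal(a.inverse, b.inverse)

    def test_jacobian_positive_for_phantom_scale_motion(self, lv_image, lv_mask):
        moving = warp(lv_image, uniform_field(lv_image.shape, dr=5.0))
        pair = register_pair(lv_image, moving)
        jac = jacobian_determinant(pair.forward)
        assert (jac[lv_mask] > 0).mean() >= 0.995

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share a 2-D shape"):
            register_pair(np.zeros((8, 8)), np.zeros((9, 8)))


def _smooth_random_field(shape, seed, amplitude=3.0):
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(0, 1, (2, *shape)), (0, 8, 8))
    f *= amplitude / max(np.abs(f).max(), 1e-9)
    return f


class TestOracleEquivalence:
    def test_endpoint_error_close_to_sitk_demons(self, lv_image, lv_mask):
        """On smooth synthetic warps, mean endpoint error must stay within
        1.5x that of SimpleITK's diffeomorphic demons at comparable settings."""
        sitk = pytest.importorskip("SimpleITK")

        ours, theirs = [], []
        for seed in range(10):
            true = _smooth_random_field(lv_image.shape, seed)
            moving = warp(lv_image, true)

            pair = register_pair(lv_image, moving)
            resid = compose(true, pair.forward)
            ours.append(np.hypot(*resid)[lv_mask].mean())

            f_img = sitk.GetImageFromArray(lv_image)
            m_img = sitk.GetImageFromArray(moving)
            reg = sitk.DiffeomorphicDemonsRegistrationFilter()
            reg.SetNumberOfIterations(80)
            reg.SetSmoothDisplacementField(True)
            reg.SetStandardDeviations(2.0)
            disp = reg.Execute(f_img, m_img)
            d = sitk.GetArrayFromImage(disp)  # (rows, cols, [x=col, y=row])
            sitk_fwd = np.stack([d[..., 1], d[..., 0]])
            resid_s = compose(true, sitk_fwd)
            theirs.append(np.hypot(*resid_s)[lv_mask].mean())

        assert np.mean(ours) <= 1.5 * np.mean(theirs), (np.mean(ours), np.mean(theirs))
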