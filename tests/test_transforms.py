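"""Transform types: composition, application, inversion, serialization."""

import numpy as np
import pytest

from neotemplate.transforms import (AffineTransform, CompositeTransform,
                                    DiffeoTransform, apply_transform,
                                    compose_transforms,
                                    invert_displacement_field,
                                    jacobian_determinant, load_transform,
                                    save_transform)
from neotemplate.volume import BinaryMask, Volume


@pytest.fixture()
def vol():
    """Compactly supported blob pattern (zero background, like a cleaned
    head image) so out-of-field fill matches the background."""
    rng = np.random.default_rng(0)
    from scipy import ndimage
    data = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2)
    idx = np.indices((24, 24, 24)).astype(float) - 11.5
    r2 = (idx ** 2).sum(axis=0)
    data *= np.exp(-r2 / 40.0)           # decays to ~0 at the boundary
    data[r2 > 100] = 0.0
    return Volume(data, spacing=(2, 2, 2), origin=(-23, -23, -23))


def smooth_field(grid, seed=1, amp=3.0, smooth=4.0):
    rng = np.random.default_rng(seed)
    from scipy import ndimage
    f = np.stack([ndimage.gaussian_filter(rng.normal(size=grid.shape),
                                          smooth) for _ in range(3)], -1)
    return f * amp / np.abs(np.linalg.norm(f, axis=-1)).max()


class TestAffine:
    def test_inverse_composes_to_identity(self):
        rng = np.random.default_rng(2)
        m = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        t = AffineTransform(m, rng.normal(size=3))
        ident = t.compose_affine(t.inverse())
        assert np.abs(ident.matrix - np.eye(3)).max() < 1e-6
        assert np.abs(ident.translation).max() < 1e-6

    def test_orientation_preserving_enforced(self):
        with pytest.raises(ValueError):
            AffineTransform(np.diag([-1.0, 1.0, 1.0]))


class TestApply:
    def test_identity_linear(self, vol):
        out = apply_transform(vol, AffineTransform.identity())
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_identity_nearest_exact(self, vol):
        out = apply_transform(vol, AffineTransform.identity(),
                              interp="nearest")
        np.testing.assert_array_equal(out.data, vol.data)

    def test_integer_shift_nearest_is_exact_shift(self, vol):
        # pull map x -> x + 2 voxels along axis 0: output[i] = input[i+1]
        t = AffineTransform(np.eye(3), [2.0, 0.0, 0.0])
        out = apply_transform(vol, t, interp="nearest", fill=-7.0)
        np.testing.assert_array_equal(out.data[:-1], vol.data[1:])
        assert np.all(out.data[-1] == -7.0)  # fill, not circular wrap

    def test_mask_stays_binary_under_nearest(self, vol):
        mask = BinaryMask.from_bool(vol.data > 0, vol)
        out = apply_transform(mask, AffineTransform(np.eye(3), [2, 0, 0]),
                              interp="nearest", fill=0)
        assert isinstance(out, BinaryMask)

    def test_sequential_equals_composed(self, vol):
        t1 = AffineTransform(np.eye(3), [3.0, -2.0, 1.0])
        ang = 0.1
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        t2 = AffineTransform(rot, [0.0, 1.0, 0.0])
        seq = apply_transform(apply_transform(vol, t1, fill=0.0), t2,
                              fill=0.0)
        comp = apply_transform(vol, compose_transforms([t1, t2]), fill=0.0)
        dyn = vol.data.max() - vol.data.min()
        assert np.abs(seq.data - comp.data).mean() < 0.01 * dyn


class TestCompose:
    def test_empty_list_is_identity(self, vol):
        t = compose_transforms([])
        pts = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(t.map_points(pts), pts)

    def test_single_identity(self):
        t = compose_transforms([AffineTransform.identity()])
        pts = np.random.default_rng(3).normal(size=(10, 3))
        np.testing.assert_allclose(t.map_points(pts), pts, atol=1e-12)

    def test_affine_with_inverse_is_identity(self):
        rng = np.random.default_rng(4)
        a = AffineTransform(np.eye(3) + 0.05 * rng.normal(size=(3, 3)),
                            rng.normal(size=3))
        t = compose_transforms([a, a.inverse()])
        pts = rng.normal(size=(20, 3)) * 10
        np.testing.assert_allclose(t.map_points(pts), pts, atol=1e-6)


class TestDiffeo:
    def test_forward_inverse_residual(self, vol):
        f = smooth_field(vol)
        inv = invert_displacement_field(f, vol)
        d = DiffeoTransform(f, inv, vol)
        idx = np.indices(vol.shape).reshape(3, -1).T.astype(float)
        pts = vol.index_to_world(idx)
        round_trip = d.map_points(d.map_points_inverse(pts))
        res = np.linalg.norm(round_trip - pts, axis=1) / vol.spacing.mean()
        assert res.mean() < 0.1
        assert res.max() < 0.5

    def test_jacobian_of_identity_field_is_one(self, vol):
        jac = jacobian_determinant(np.zeros(tuple(vol.shape) + (3,)), vol)
        np.testing.assert_allclose(jac, 1.0, atol=1e-12)

    def test_jacobian_positive_for_smooth_field(self, vol):
        assert jacobian_determinant(smooth_field(vol), vol).min() > 0

    def test_field_shape_validated(self, vol):
        with pytest.raises(Exception):
            DiffeoTransform(np.zeros((4, 4, 4, 3)),
                            np.zeros((4, 4, 4, 3)), vol)


class TestSerialization:
    def test_affine_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        t = AffineTransform(np.eye(3) + 0.05 * rng.normal(size=(3, 3)),
                            rng.normal(size=3))
        save_transform(t, tmp_path / "a.txt")
        back = load_transform(tmp_path / "a.txt")
        np.testing.assert_allclose(back.matrix, t.matrix, atol=1e-12)
        np.testing.assert_allclose(back.translation, t.translation,
                                   atol=1e-12)

    def test_diffeo_round_trip(self, tmp_path, vol):
        f = smooth_field(vol)
        d = DiffeoTransform(f, invert_displacement_field(f, vol), vol)
        save_transform(d, tmp_path / "d")
        back = load_transform(tmp_path / "d")
        np.testing.assert_allclose(back.forward, d.forward, atol=1e-6)
        np.testing.assert_allclose(back.inverse, d.inverse, atol=1e-6)

    def test_composite_round_trip_preserves_order(self, tmp_path, vol):
        a = AffineTransform(np.eye(3), [1.0, 2.0, 3.0])
        f = smooth_field(vol)
        d = DiffeoTransform(f, invert_displacement_field(f, vol), vol)
        c = compose_transforms([a, d])
        save_transform(c, tmp_path / "c")
        back = load_transform(tmp_path / "c")
        assert isinstance(back.transforms[0], AffineTransform)
        assert isinstance(back.transforms[1], DiffeoTransform)
        pts = np.random.default_rng(6).normal(size=(10, 3)) * 5
        np.testing.assert_allclose(back.map_points(pts), c.map_points(pts),
                                   atol=1e-5)
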