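"""Volume container, NIfTI round trips, resampling, smoothing, rigid init."""

import numpy as np
import pytest

from neotemplate.volume import (BinaryMask, DegenerateInputError, FormatError,
                                Volume, fwhm_to_sigma, gaussian_smooth,
                                read_volume, resample_isotropic,
                                rigid_initialize, write_volume)


def random_volume(rng, shape=(16, 16, 16), spacing=(0.47, 0.47, 0.47)):
    return Volume(rng.normal(size=shape), spacing, origin=(1.0, -2.0, 3.0))


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = random_volume(rng)
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-5)
        np.testing.assert_allclose(back.direction, vol.direction, atol=1e-6)

    def test_header_spacing_round_trip(self, tmp_path):
        vol = Volume(np.zeros((8, 8, 8)), spacing=(0.47, 0.47, 0.47))
        write_volume(vol, tmp_path / "s.nii.gz")
        assert np.allclose(read_volume(tmp_path / "s.nii.gz").spacing, 0.47)

    def test_mask_values_on_disk(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = random_volume(rng, shape=(8, 8, 8))
        mask = BinaryMask.from_bool(vol.data > 0, vol)
        write_volume(mask, tmp_path / "m.nii.gz")
        assert set(np.unique(read_volume(tmp_path / "m.nii.gz").data)) <= {0, 1}

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_non_3d_file_errors(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((8, 8)), np.eye(4)),
                 str(tmp_path / "flat.nii.gz"))
        with pytest.raises(FormatError):
            read_volume(tmp_path / "flat.nii.gz")

    def test_2d_data_rejected_by_container(self):
        with pytest.raises(FormatError):
            Volume(np.zeros((4, 4)))


class TestResample:
    def test_identity_resample(self):
        rng = np.random.default_rng(2)
        vol = Volume(rng.normal(size=(12, 12, 12)), spacing=(1, 1, 1))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_constant_stays_constant(self):
        vol = Volume(np.full((10, 14, 8), 7.0), spacing=(0.47, 0.47, 0.7))
        out = resample_isotropic(vol, 0.47)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-9)
        assert np.allclose(out.spacing, 0.47)

    def test_world_ramp_matches_analytic(self):
        # f(x) = x (world mm along axis 0): linear interpolation is exact on
        # a linear function, up to edge handling
        shape = (20, 8, 8)
        spacing = np.array([2.0, 2.0, 2.0])
        idx = np.indices(shape).astype(float)
        vol = Volume(idx[0] * spacing[0], spacing)
        out = resample_isotropic(vol, 1.0)
        expected = np.indices(out.shape).astype(float)[0] * 1.0
        interior = (slice(0, -2), slice(None), slice(None))
        np.testing.assert_allclose(out.data[interior], expected[interior],
                                   atol=1e-3)

    def test_nearest_keeps_mask_binary(self):
        rng = np.random.default_rng(3)
        vol = Volume(rng.normal(size=(10, 10, 10)), spacing=(2, 2, 3))
        mask = BinaryMask.from_bool(vol.data > 0, vol)
        out = resample_isotropic(mask, 1.5, interp="nearest")
        assert isinstance(out, BinaryMask)

    def test_range_not_expanded(self):
        rng = np.random.default_rng(4)
        vol = Volume(rng.uniform(-5, 5, size=(10, 10, 10)),
                     spacing=(1, 1, 2))
        out = resample_isotropic(vol, 0.8)
        assert out.data.min() >= vol.data.min() - 1e-9
        assert out.data.max() <= vol.data.max() + 1e-9

    def test_bad_spacing_errors(self):
        vol = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(5)
        vol = Volume(rng.normal(size=(8, 8, 8)))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0).data,
                                      vol.data)

    def test_impulse_matches_analytic_kernel(self):
        # unit impulse, FWHM 2 mm at 1 mm spacing: response is the separable
        # discrete Gaussian with sigma = 2 / (2 sqrt(2 ln 2)) voxels
        shape = (33, 33, 33)
        vol = Volume(np.zeros(shape), spacing=(1, 1, 1))
        vol.data[16, 16, 16] = 1.0
        out = gaussian_smooth(vol, 2.0)
        sigma = fwhm_to_sigma(2.0)
        offsets = np.arange(-16, 17)
        k1 = np.exp(-offsets ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_allclose(out.data, expected, atol=1e-4)

    def test_mass_conserved_for_interior_blob(self):
        vol = Volume(np.zeros((32, 32, 32)), spacing=(1, 1, 1))
        vol.data[12:20, 12:20, 12:20] = 3.0
        out = gaussian_smooth(vol, 2.0)
        assert abs(out.data.sum() - vol.data.sum()) < 1e-6 * vol.data.sum()

    def test_commutes_with_scaling(self):
        rng = np.random.default_rng(6)
        vol = Volume(rng.normal(size=(12, 12, 12)))
        a = 3.7
        lhs = gaussian_smooth(vol.with_data(a * vol.data), 2.0).data
        rhs = a * gaussian_smooth(vol, 2.0).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_negative_fwhm_errors(self):
        with pytest.raises(ValueError):
            gaussian_smooth(Volume(np.zeros((4, 4, 4))), -1.0)


class TestRigidInitialize:
    def test_self_alignment_is_identity(self, phantom48):
        t = rigid_initialize(phantom48.ct, phantom48.ct)
        assert np.abs(t.matrix - np.eye(3)).max() < 1e-3
        assert np.abs(t.translation).max() < 1e-3

    def test_translation_recovered(self, phantom48):
        vol = phantom48.ct
        shifted = Volume(vol.data, vol.spacing, vol.origin + [10.0, 0, 0],
                         vol.direction)
        t = rigid_initialize(shifted, vol)
        # pull transform maps fixed points onto moving points: +10 mm
        assert abs(t.translation[0] - 10.0) < vol.spacing[0]
        assert np.abs(t.translation[1:]).max() < vol.spacing[0]

    def test_rotation_recovered(self, phantom48):
        from neotemplate.transforms import AffineTransform, apply_transform
        vol = phantom48.ct
        ang = np.deg2rad(10.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = apply_transform(vol, AffineTransform(rot.T), fill=-1000.0)
        t = rigid_initialize(rotated, vol)
        angle = np.rad2deg(np.arccos(
            np.clip((np.trace(t.matrix) - 1) / 2, -1, 1)))
        assert abs(angle - 10.0) < 2.0

    def test_constant_image_errors(self):
        flat = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(DegenerateInputError):
            rigid_initialize(flat, flat)


class TestInvariants:
    def test_direction_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), direction=np.eye(3) * 2)

    def test_spacing_must_be_positive(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), spacing=(1, -1, 1))

    def test_mask_rejects_non_binary(self):
        with pytest.raises(ValueError):
            BinaryMask(np.full((4, 4, 4), 0.5))
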