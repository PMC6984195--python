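import struct

import numpy as np
import pytest

from vsdir.volume_io import (
    FormatError,
    Volume3D,
    physical_to_voxel,
    read_deformation_field,
    read_volume,
    resample_to_grid,
    voxel_to_physical,
    write_deformation_field,
    write_volume,
)

from conftest import write_dicom_slice


class TestVolume3D:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            Volume3D(data=np.zeros((4, 4, 4)), spacing=np.array([1.0, 0.0, 1.0]))

    def test_rejects_non3d(self):
        with pytest.raises(ValueError, match="3D"):
            Volume3D(data=np.zeros((4, 4)), spacing=np.ones(3))

    def test_dims_match_data(self, small_volume):
        assert small_volume.dims == small_volume.data.shape


class TestCoordinateMaps:
    def test_origin_maps_to_zero_index(self, small_volume):
        np.testing.assert_allclose(
            physical_to_voxel(small_volume, small_volume.origin), [0, 0, 0], atol=1e-12
        )

    def test_origin_plus_spacing_is_index_one(self, small_volume):
        p = small_volume.origin + small_volume.spacing
        np.testing.assert_allclose(physical_to_voxel(small_volume, p), [1, 1, 1], atol=1e-12)

    def test_round_trip_random_points(self, small_volume, rng):
        pts = rng.uniform(-50, 50, size=(100, 3))
        for p in pts:
            back = voxel_to_physical(small_volume, physical_to_voxel(small_volume, p))
            assert np.linalg.norm(back - p) < 1e-9


class TestNiftiRoundTrip:
    def test_constant_volume_identity(self, tmp_path):
        vol = Volume3D(data=np.full((8, 8, 8), 7, dtype=np.int16), spacing=np.ones(3))
        write_volume(vol, tmp_path / "v.nii")
        back = read_volume(tmp_path / "v.nii")
        np.testing.assert_array_equal(back.data, vol.data)
        np.testing.assert_allclose(back.spacing, vol.spacing)

    def test_float_round_trip(self, tmp_path, small_volume):
        write_volume(small_volume, tmp_path / "v.nii")
        back = read_volume(tmp_path / "v.nii")
        assert np.max(np.abs(back.data - small_volume.data)) <= 1e-6
        np.testing.assert_allclose(back.origin, small_volume.origin, atol=1e-5)

    def test_int16_ct_range_bit_exact(self, tmp_path, rng):
        data = rng.integers(-1024, 3072, size=(12, 10, 8)).astype(np.int16)
        vol = Volume3D(data=data, spacing=np.array([1.17, 1.17, 3.0]))
        write_volume(vol, tmp_path / "ct.nii")
        back = read_volume(tmp_path / "ct.nii")
        np.testing.assert_array_equal(back.data, data)

    def test_spacing_against_independent_header_parse(self, tmp_path):
        # oracle: pull pixdim straight out of the NIfTI-1 binary header
        vol = Volume3D(
            data=np.zeros((6, 6, 6), dtype=np.int16), spacing=np.array([1.17, 1.17, 3.0])
        )
        write_volume(vol, tmp_path / "v.nii")
        with open(tmp_path / "v.nii", "rb") as fh:
            hdr = fh.read(348)
        pixdim = struct.unpack_from("<8f", hdr, 76)
        np.testing.assert_allclose(pixdim[1:4], [1.17, 1.17, 3.0], rtol=1e-6)
        back = read_volume(tmp_path / "v.nii")
        np.testing.assert_allclose(back.spacing, pixdim[1:4], rtol=1e-6)

    def test_write_to_missing_directory_leaves_no_partial_file(self, tmp_path, small_volume):
        target = tmp_path / "nonexistent" / "v.nii"
        with pytest.raises((IOError, OSError)):
            write_volume(small_volume, target)
        assert not target.exists()


class TestMetaImage:
    def test_round_trip_float(self, tmp_path, small_volume):
        write_volume(small_volume, tmp_path / "v.mhd")
        back = read_volume(tmp_path / "v.mhd")
        assert np.max(np.abs(back.data - small_volume.data)) <= 1e-6
        np.testing.assert_allclose(back.spacing, small_volume.spacing)
        np.testing.assert_allclose(back.origin, small_volume.origin)

    def test_round_trip_int16(self, tmp_path, rng):
        data = rng.integers(-1024, 3072, size=(9, 7, 5)).astype(np.int16)
        vol = Volume3D(data=data, spacing=np.array([0.5, 0.5, 2.0]), origin=np.array([1, 2, 3.0]))
        write_volume(vol, tmp_path / "v.mhd")
        back = read_volume(tmp_path / "v.mhd")
        np.testing.assert_array_equal(back.data, data)

    def test_missing_field_reports_name(self, tmp_path):
        (tmp_path / "bad.mhd").write_text("NDims = 3\nDimSize = 4 4 4\n")
        with pytest.raises(FormatError, match="ElementType"):
            read_volume(tmp_path / "bad.mhd")

    def test_size_mismatch_rejected(self, tmp_path):
        (tmp_path / "bad.mhd").write_text(
            "NDims = 3\nDimSize = 4 4 4\nElementType = MET_SHORT\nElementDataFile = bad.raw\n"
        )
        (tmp_path / "bad.raw").write_bytes(b"\x00" * 10)
        with pytest.raises(FormatError, match="raw size"):
            read_volume(tmp_path / "bad.mhd")

    def test_unsupported_write_format(self, tmp_path, small_volume):
        with pytest.raises(FormatError, match="unsupported"):
            write_volume(small_volume, tmp_path / "v.xyz", format="analyze")


class TestDicomSeries:
    def _write_series(self, directory, data, spacing=(1.0, 1.0, 2.0), shuffle_names=False):
        nz = data.shape[2]
        order = np.arange(nz)
        names = [f"slice_{i:03d}.dcm" for i in range(nz)]
        if shuffle_names:
            names = names[::-1]  # file names out of position order
        for k, name in zip(order, names):
            write_dicom_slice(
                directory / name,
                data[:, :, k],
                position=(0.0, 0.0, k * spacing[2]),
                pixel_spacing=spacing[:2],
            )

    def test_reads_series(self, tmp_path, rng):
        data = rng.integers(-1000, 1000, size=(8, 6, 5)).astype(np.int16)
        self._write_series(tmp_path, data)
        vol = read_volume(tmp_path, format="dicom_series")
        np.testing.assert_array_equal(vol.data, data)
        np.testing.assert_allclose(vol.spacing, [1.0, 1.0, 2.0])

    def test_slices_sorted_by_position_not_name(self, tmp_path, rng):
        data = rng.integers(0, 500, size=(6, 6, 4)).astype(np.int16)
        self._write_series(tmp_path, data, shuffle_names=True)
        vol = read_volume(tmp_path, format="dicom_series")
        np.testing.assert_array_equal(vol.data, data)

    def test_mixed_spacing_rejected(self, tmp_path, rng):
        data = rng.integers(0, 100, size=(4, 4, 2)).astype(np.int16)
        write_dicom_slice(tmp_path / "a.dcm", data[:, :, 0], position=(0, 0, 0), pixel_spacing=(1, 1))
        write_dicom_slice(
            tmp_path / "b.dcm", data[:, :, 1], position=(0, 0, 2), pixel_spacing=(1.5, 1.5)
        )
        with pytest.raises(FormatError, match="mixed"):
            read_volume(tmp_path, format="dicom_series")

    def test_rescale_slope_intercept_applied(self, tmp_path):
        raw = np.arange(16, dtype=np.int16).reshape(4, 4)
        write_dicom_slice(tmp_path / "a.dcm", raw, slope=2.0, intercept=-1000.0)
        vol = read_volume(tmp_path, format="dicom_series")
        np.testing.assert_allclose(vol.data[:, :, 0], raw * 2.0 - 1000.0)


class TestResample:
    def test_identity_when_grids_match(self, small_volume):
        out = resample_to_grid(small_volume, small_volume, fill=0.0)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_zero_padding_outside_extent(self, rng):
        moving = Volume3D(data=rng.uniform(10, 20, size=(32, 32, 32)), spacing=np.ones(3))
        target = Volume3D(
            data=np.zeros((64, 64, 64)), spacing=np.ones(3), origin=np.array([-16.0, -16.0, -16.0])
        )
        out = resample_to_grid(moving, target, fill=0.0)
        assert out.dims == (64, 64, 64)
        assert np.all(out.data[:15] == 0.0) and np.all(out.data[48:] == 0.0)
        assert np.all(out.data[16:48, 16:48, 16:48] >= 10.0)

    def test_constant_volume_interior_constant(self):
        moving = Volume3D(data=np.full((20, 20, 20), 5.5), spacing=np.ones(3))
        target = Volume3D(data=np.zeros((10, 10, 10)), spacing=np.full(3, 1.5))
        out = resample_to_grid(moving, target, fill=0.0)
        np.testing.assert_allclose(out.data[:9, :9, :9], 5.5)

    def test_origin_offset_shifts_content(self):
        moving = Volume3D(data=np.zeros((10, 10, 10)), spacing=np.ones(3))
        moving.data[5, 5, 5] = 100.0
        out = resample_to_grid(moving, moving, fill=0.0, origin_offset=(1.0, 0.0, 0.0))
        assert out.data[6, 5, 5] == pytest.approx(100.0)


class TestDeformationFieldIO:
    def test_round_trip(self, tmp_path, small_volume, rng):
        disp = rng.normal(0, 2, size=small_volume.dims + (3,))
        write_deformation_field(disp, small_volume, tmp_path / "f.nii")
        back, grid = read_deformation_field(tmp_path / "f.nii")
        np.testing.assert_allclose(back, disp, atol=1e-12)
        np.testing.assert_allclose(grid.spacing, small_volume.spacing)

    def test_shape_mismatch_rejected(self, tmp_path, small_volume):
        with pytest.raises(ValueError, match="match"):
            write_deformation_field(np.zeros((2, 2, 2, 3)), small_volume, tmp_path / "f.nii")
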