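import json

import numpy as np
import pytest

from theradose.grids import RoiSet, ScalarVolume, VoxelGrid, resample_to_reference
from theradose.io import read_manifest, read_volume, write_manifest, write_volume


class TestVoxelGrid:
    def test_voxel_volume(self):
        g = VoxelGrid((8, 8, 8), (4.0, 4.0, 4.0))
        assert g.voxel_volume_mm3 == 64.0
        assert g.voxel_volume_ml == pytest.approx(0.064)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            VoxelGrid((0, 4, 4))
        with pytest.raises(ValueError):
            VoxelGrid((4, 4, 4), (0.0, 4.0, 4.0))

    def test_world_coordinates_are_voxel_centers(self):
        g = VoxelGrid((3, 3, 3), (2.0, 2.0, 2.0), origin=(1.0, 0.0, 0.0))
        x, y, z = g.coordinate_axes()
        np.testing.assert_allclose(x, [1.0, 3.0, 5.0])
        np.testing.assert_allclose(y, [0.0, 2.0, 4.0])


class TestScalarVolume:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ScalarVolume(VoxelGrid((4, 4, 4)), np.zeros((4, 4, 5)), "Bq/mL")

    def test_negative_activity_rejected_with_index(self):
        data = np.zeros((4, 4, 4))
        data[1, 2, 3] = -5.0
        with pytest.raises(ValueError, match=r"\(1, 2, 3\)"):
            ScalarVolume(VoxelGrid((4, 4, 4)), data, "Bq/mL")

    def test_unknown_units_rejected(self):
        with pytest.raises(ValueError, match="units"):
            ScalarVolume(VoxelGrid((4, 4, 4)), np.zeros((4, 4, 4)), "furlongs")

    def test_units_guard(self):
        v = ScalarVolume(VoxelGrid((4, 4, 4)), np.zeros((4, 4, 4)), "Gy")
        with pytest.raises(ValueError, match="Bq/mL"):
            v.require_units("Bq/mL")


class TestVolumeRoundTrip:
    def test_round_trip_values_and_grid(self, tmp_path):
        rng = np.random.default_rng(3)
        g = VoxelGrid((6, 5, 4), (2.0, 3.0, 4.0), origin=(1.0, -2.0, 0.5))
        v = ScalarVolume(g, rng.random((6, 5, 4)).astype(np.float32), "Bq/mL",
                         timestamp=4.0, nuclide_tag="Zr-89")
        p = tmp_path / "v.nii.gz"
        write_volume(v, p)
        back = read_volume(p)
        np.testing.assert_array_equal(back.values, v.values)
        assert back.grid == g
        assert back.units == "Bq/mL"
        assert back.timestamp == 4.0
        assert back.nuclide_tag == "Zr-89"

    def test_negative_voxel_rejected_on_write(self, tmp_path):
        v = ScalarVolume(VoxelGrid((4, 4, 4)), np.zeros((4, 4, 4)), "Gy")
        v.values[2, 0, 1] = -1.0  # mutate after construction
        with pytest.raises(ValueError, match=r"\(2, 0, 1\)"):
            write_volume(v, tmp_path / "bad.nii.gz")

    def test_missing_sidecar_rejected(self, tmp_path):
        v = ScalarVolume(VoxelGrid((4, 4, 4)), np.zeros((4, 4, 4)), "Bq/mL", timestamp=4.0)
        p = tmp_path / "v.nii.gz"
        sidecar = write_volume(v, p)
        sidecar.unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            read_volume(p)

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "flat.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), str(p))
        (tmp_path / "flat.json").write_text(json.dumps({"units": "Bq/mL"}))
        with pytest.raises(ValueError, match="3-D"):
            read_volume(p)


class TestResample:
    def _labels(self):
        g = VoxelGrid((8, 8, 8), (4.0, 4.0, 4.0))
        lab = np.zeros((8, 8, 8), dtype=np.int16)
        lab[2:6, 2:6, 2:6] = 3
        return ScalarVolume(g, lab, "1")

    def test_identity(self):
        v = self._labels()
        out = resample_to_reference(v, v.grid, "nearest")
        np.testing.assert_array_equal(out.values, v.values)

    def test_label_trilinear_rejected(self):
        with pytest.raises(ValueError, match="nearest"):
            resample_to_reference(self._labels(), VoxelGrid((4, 4, 4), (8.0, 8.0, 8.0)), "trilinear")

    def test_nearest_introduces_no_new_labels(self):
        v = self._labels()
        ref = VoxelGrid((5, 5, 5), (6.0, 6.0, 6.0), origin=(1.0, 1.0, 1.0))
        out = resample_to_reference(v, ref, "nearest")
        assert set(np.unique(out.values)) <= set(np.unique(v.values))

    def test_uniform_field_downsampled_stays_uniform(self):
        g = VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0))
        v = ScalarVolume(g, np.ones(g.shape), "Bq/mL", timestamp=1.0)
        ref = VoxelGrid((8, 8, 8), (4.0, 4.0, 4.0), origin=(1.0, 1.0, 1.0))
        out = resample_to_reference(v, ref, "trilinear")
        np.testing.assert_allclose(out.values[1:-1, 1:-1, 1:-1], 1.0, rtol=1e-6)

    def test_trilinear_conserves_interior_total_within_1pct(self):
        rng = np.random.default_rng(5)
        g = VoxelGrid((20, 20, 20), (2.0, 2.0, 2.0))
        vals = np.zeros(g.shape)
        vals[6:14, 6:14, 6:14] = rng.random((8, 8, 8)) + 0.5
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(vals, 1.5)  # smooth, interior-supported
        v = ScalarVolume(g, vals, "Bq/mL", timestamp=1.0)
        ref = VoxelGrid((10, 10, 10), (4.0, 4.0, 4.0), origin=(1.0, 1.0, 1.0))
        out = resample_to_reference(v, ref, "trilinear")
        assert out.total() == pytest.approx(v.total(), rel=0.01)


class TestRoiSet:
    def test_names_must_exist_in_volume(self):
        g = VoxelGrid((4, 4, 4))
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        lab[0, 0, 0] = 1
        with pytest.raises(ValueError, match="absent"):
            RoiSet(ScalarVolume(g, lab, "1"), {1: "a", 2: "ghost"})

    def test_background_label_reserved(self):
        g = VoxelGrid((4, 4, 4))
        lab = np.zeros((4, 4, 4), dtype=np.int16)
        with pytest.raises(ValueError, match="background"):
            RoiSet(ScalarVolume(g, lab, "1"), {0: "bg"})


class TestManifest:
    def test_round_trip_default_phantom(self, tmp_path, phantom_default):
        path = write_manifest(phantom_default, tmp_path / "study")
        bundle = read_manifest(path)
        assert [f.timestamp for f in bundle.frames] == [4.0, 24.0, 48.0, 73.0]
        assert bundle.meta.injected_activity_mbq == pytest.approx(9.88)
        assert bundle.imaging_nuclide == "Zr-89"
        assert sorted(bundle.labels.labels) == sorted(phantom_default.labels.labels)
        np.testing.assert_allclose(
            bundle.frames[0].values, phantom_default.frames[0].values, rtol=1e-6
        )

    def test_out_of_order_frames_rejected(self, tmp_path, phantom_default):
        path = write_manifest(phantom_default, tmp_path / "study")
        raw = json.loads(path.read_text())
        raw["frames"][0], raw["frames"][1] = raw["frames"][1], raw["frames"][0]
        path.write_text(json.dumps(raw))
        with pytest.raises(ValueError, match="24.0 then 4.0"):
            read_manifest(path)

    def test_missing_required_field_rejected(self, tmp_path, phantom_default):
        path = write_manifest(phantom_default, tmp_path / "study")
        raw = json.loads(path.read_text())
        del raw["injected_activity_mbq"]
        path.write_text(json.dumps(raw))
        with pytest.raises(ValueError, match="injected_activity_mbq"):
            read_manifest(path)
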