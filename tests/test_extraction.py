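"""CT loading, coordinate mapping and patch cropping."""

import numpy as np
import pytest

from micronod.annotations import SliceRef, parse_annotation_xml
from micronod.extraction import (
    AIR_HU,
    CTVolume,
    Patch,
    SliceResolutionError,
    build_patch_dataset,
    extract_patch,
    load_ct_series,
    map_mark_to_voxel,
    normalize_patch,
    patches_to_arrays,
)
from micronod.synthetic import FixturePlan, PlantedMark, generate_scan_fixture


@pytest.fixture()
def volume():
    rng = np.random.default_rng(0)
    vox = rng.uniform(-1000, 400, size=(64, 64, 3))
    return CTVolume(voxels=vox, pixel_spacing=(0.7, 0.7),
                    slice_z=np.array([0.0, 2.5, 5.0]),
                    slice_uids=["U0", "U1", "U2"])


@pytest.fixture(scope="module")
def scan_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    plan = FixturePlan(
        shape=(64, 64, 3),
        marks=[
            PlantedMark("micro_nodule", 20, 30, 0),
            PlantedMark("micro_nodule", 40, 12, 1),
            PlantedMark("non_nodule", 50, 50, 2),
            PlantedMark("nodule", 32, 32, 1),
        ],
        seed=5,
    )
    manifest = generate_scan_fixture(plan, out)
    return plan, out, manifest


class TestLoadCTSeries:
    def test_slices_sorted_by_z_and_hu_converted(self, scan_fixture):
        plan, out, _ = scan_fixture
        files = sorted((out / "dicom").glob("*.dcm"))
        vol = load_ct_series(reversed(files))  # out of order on purpose
        assert vol.voxels.shape == (64, 64, 3)
        assert np.allclose(vol.slice_z, [0.0, 2.5, 5.0])
        # stored 0 with slope 1 / intercept -1024 would be -1024 HU; the
        # fixture background sits in lung-parenchyma HU range
        assert -1024 <= vol.voxels.min() < -500

    def test_hu_rescale_oracle(self, scan_fixture, tmp_path):
        """HU = raw*slope + intercept, against pydicom's own fields."""
        import pydicom
        _, out, _ = scan_fixture
        path = sorted((out / "dicom").glob("*.dcm"))[0]
        ds = pydicom.dcmread(path)
        raw = ds.pixel_array.astype(float)
        vol = load_ct_series([path])
        expected = raw * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        assert np.allclose(vol.voxels[:, :, 0], expected)

    def test_single_slice_series(self, scan_fixture):
        _, out, _ = scan_fixture
        path = sorted((out / "dicom").glob("*.dcm"))[0]
        vol = load_ct_series([path])
        assert vol.n_slices == 1

    def test_mixed_series_rejected(self, scan_fixture, tmp_path):
        plan, out, _ = scan_fixture
        other = FixturePlan(shape=(64, 64, 1), patient_id="SYN-0002", seed=9)
        generate_scan_fixture(other, tmp_path)
        files = list((out / "dicom").glob("*.dcm")) + \
            list((tmp_path / "dicom").glob("*.dcm"))
        with pytest.raises(ValueError, match="mixed series"):
            load_ct_series(files)


class TestMapMarkToVoxel:
    def test_exact_sop_match(self, volume):
        rcs = map_mark_to_voxel((10, 20, SliceRef("U2", None)), volume)
        assert rcs == (20, 10, 2)  # x is the column axis

    def test_nearest_z_within_tolerance(self, volume):
        assert map_mark_to_voxel((5, 6, SliceRef(None, 2.4)), volume)[2] == 1

    def test_z_within_half_spacing_boundary_accepted(self, volume):
        # 1.2 mm sits 1.2 mm from slice 0, inside the 1.25 mm tolerance
        assert map_mark_to_voxel((5, 6, SliceRef(None, 1.2)), volume)[2] == 0

    def test_z_outside_half_spacing_errors(self, volume):
        with pytest.raises(SliceResolutionError, match="mm"):
            map_mark_to_voxel((5, 6, SliceRef(None, 6.9)), volume)


class TestExtractPatch:
    def test_interior_crop(self, volume):
        patch = extract_patch(volume, (32, 32, 0), 16)
        assert np.array_equal(patch, volume.voxels[24:40, 24:40, 0])

    def test_corner_crop_equals_pad_then_crop(self, volume):
        """Oracle: pre-pad the slice with air on all sides, then crop."""
        size = 16
        padded = np.pad(volume.voxels[:, :, 0], size,
                        constant_values=AIR_HU)
        for center in [(0, 0), (63, 63), (2, 60)]:
            got = extract_patch(volume, (*center, 0), size)
            r, c = center[0] + size, center[1] + size
            expected = padded[r - size // 2:r + size // 2,
                              c - size // 2:c + size // 2]
            assert np.array_equal(got, expected)

    def test_nesting_16_in_32_in_64(self, volume):
        center = (10, 55, 1)  # near a border so padding is exercised too
        p16 = extract_patch(volume, center, 16)
        p32 = extract_patch(volume, center, 32)
        p64 = extract_patch(volume, center, 64)
        assert np.array_equal(p64[16:48, 16:48], p32)
        assert np.array_equal(p32[8:24, 8:24], p16)


class TestNormalizePatch:
    @pytest.mark.parametrize("hu,expected", [
        (-1500.0, 0.0),   # below window, clipped
        (-1000.0, 0.0),
        (-300.0, 0.5),    # window midpoint
        (400.0, 1.0),
        (900.0, 1.0),     # above window, clipped
    ])
    def test_affine_window(self, hu, expected):
        assert normalize_patch(np.full((4, 4), hu)) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_patch(np.array([[np.nan]]))


class TestBuildPatchDataset:
    def test_counts_centers_and_nodule_exclusion(self, scan_fixture):
        plan, out, _ = scan_fixture
        scan = parse_annotation_xml(
            next((out / "xml").glob("*.xml")).read_text()
        )
        volume = load_ct_series((out / "dicom").glob("*.dcm"))
        store, manifest, skipped = build_patch_dataset(
            [scan], {scan.patient_id: volume}, sizes=(16, 32, 64)
        )
        assert skipped == []
        # 2 planted micro + 1 non-nodule, one patch each per size; the
        # contoured nodule contributes nothing
        for size in (16, 32, 64):
            labels = [p.label for p in store[size]]
            assert labels.count(1) == 2 and labels.count(0) == 1
        assert len(manifest) == 9
        planted = {(m.row, m.col, m.slice_index)
                   for m in plan.marks if m.category != "nodule"}
        got = {tuple(r) for r in
               manifest[["row", "col", "slice_index"]].drop_duplicates().values}
        assert got == planted
        # patch centre pixel equals the fixture image value at the mark
        for p in store[16]:
            row = manifest[(manifest["mark_id"] == p.mark_id)
                           & (manifest["size"] == 16)].iloc[0]
            img_val = normalize_patch(
                volume.voxels[row.row, row.col, row.slice_index])
            assert p.pixels[8, 8] == pytest.approx(float(img_val))

    def test_unresolvable_mark_skipped_and_logged(self, scan_fixture):
        plan, out, _ = scan_fixture
        scan = parse_annotation_xml(
            next((out / "xml").glob("*.xml")).read_text()
        )
        # volume whose z range cannot resolve the marks' slice refs
        bad = CTVolume(voxels=np.full((64, 64, 2), -800.0),
                       pixel_spacing=(0.7, 0.7),
                       slice_z=np.array([100.0, 102.5]),
                       slice_uids=["X0", "X1"])
        store, manifest, skipped = build_patch_dataset(
            [scan], {scan.patient_id: bad}, sizes=(16,)
        )
        assert len(store[16]) == 0 and len(manifest) == 0
        assert len(skipped) == 3  # every non-contour mark, each with reason
        assert all("mm" in s for s in skipped)

    def test_determinism(self, scan_fixture):
        _, out, _ = scan_fixture
        scan = parse_annotation_xml(next((out / "xml").glob("*.xml")).read_text())
        volume = load_ct_series((out / "dicom").glob("*.dcm"))
        a = build_patch_dataset([scan], {scan.patient_id: volume}, sizes=(32,))
        b = build_patch_dataset([scan], {scan.patient_id: volume}, sizes=(32,))
        xa, ya = patches_to_arrays(a[0][32])
        xb, yb = patches_to_arrays(b[0][32])
        assert np.array_equal(xa, xb) and np.array_equal(ya, yb)
        assert a[1].equals(b[1])


def test_patch_invariants():
    with pytest.raises(ValueError):
        Patch(pixels=np.zeros((16, 16)), size=16, label=2,
              patient_id="p", reader_index=0, mark_id="m")
    with pytest.raises(ValueError):
        Patch(pixels=np.full((16, 16), 1.5), size=16, label=1,
              patient_id="p", reader_index=0, mark_id="m")
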