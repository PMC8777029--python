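"""HU windowing, gray mapping and patch round trips."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segan3d.preprocess import (GrayVolume, HUVolume, PatchSet, WindowParams,
                                extract_patches, hu_to_gray, map_to_gray,
                                normalize_hu, read_ct_volume, resample_inplane,
                                stitch_patches, truncate_hu, write_nifti)


def _vol(values):
    return HUVolume(values=np.asarray(values, dtype=float), spacing=(1, 1, 1))


class TestWindowing:
    @pytest.mark.parametrize("hu,expected", [(-1000.0, -200.0), (0.0, 0.0),
                                             (350.0, 200.0)])
    def test_truncate_clips_into_window(self, hu, expected):
        out = truncate_hu(_vol([[[hu]]]))
        assert out.values[0, 0, 0] == expected

    def test_truncate_is_idempotent(self, rng):
        v = _vol(rng.uniform(-1200, 1200, size=(4, 5, 6)))
        once = truncate_hu(v)
        twice = truncate_hu(once)
        assert np.array_equal(once.values, twice.values)

    @pytest.mark.parametrize("hu,expected", [(-200.0, 0.0), (200.0, 1.0),
                                             (0.0, 0.5)])
    def test_normalize_linear_map(self, hu, expected):
        assert normalize_hu(_vol([[[hu]]]))[0, 0, 0] == pytest.approx(expected)

    def test_normalize_rejects_out_of_window_values(self):
        with pytest.raises(ValueError, match="truncate"):
            normalize_hu(_vol([[[300.0]]]))

    def test_window_params_must_be_ordered(self):
        with pytest.raises(ValueError):
            WindowParams(hu_min=10, hu_max=-10)

    @pytest.mark.parametrize("norm,expected", [(1.0, 255), (0.0, 0), (0.5, 127)])
    def test_gray_mapping_truncates(self, norm, expected):
        gray = map_to_gray(np.array([[[norm]]]), (1, 1, 1))
        assert gray.values[0, 0, 0] == expected

    def test_gray_mapping_round_mode(self):
        gray = map_to_gray(np.array([[[0.5]]]), (1, 1, 1), rounding="round")
        assert gray.values[0, 0, 0] == 128

    def test_gray_mapping_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            map_to_gray(np.array([[[1.5]]]), (1, 1, 1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2000, 2000), min_size=2, max_size=20))
    def test_pipeline_is_monotone_and_in_range(self, values):
        v = _vol(np.sort(np.array(values)).reshape(-1, 1, 1))
        gray = hu_to_gray(v).values.ravel()
        assert np.all(np.diff(gray.astype(int)) >= 0)
        assert gray.min() >= 0 and gray.max() <= 255

    def test_gray_volume_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            GrayVolume(values=np.full((2, 2, 2), 300), spacing=(1, 1, 1))


class TestPatching:
    def test_tiling_counts_along_z(self):
        vol = GrayVolume(values=np.zeros((256, 256, 48), dtype=np.uint8),
                         spacing=(1, 1, 1))
        ps = extract_patches(vol, (256, 256, 16))
        assert len(ps) == 3 and ps.pad_record == (0, 0, 0)

    def test_identity_tiling(self):
        vol = GrayVolume(values=np.zeros((256, 256, 16), dtype=np.uint8),
                         spacing=(1, 1, 1))
        ps = extract_patches(vol, (256, 256, 16))
        assert len(ps) == 1 and ps.pad_record == (0, 0, 0)

    def test_padding_to_next_multiple(self, rng):
        arr = rng.integers(0, 255, size=(64, 64, 20)).astype(np.uint8)
        ps = extract_patches(arr, (64, 64, 16))
        assert len(ps) == 2 and ps.pad_record == (0, 0, 12)
        assert np.array_equal(ps.patches[1][:, :, 4:], np.zeros((64, 64, 12)))

    @pytest.mark.parametrize("shape,patch", [
        ((10, 12, 7), (4, 4, 4)), ((9, 3, 5), (3, 3, 5)), ((8, 8, 8), (8, 8, 8)),
    ])
    def test_round_trip_is_exact(self, rng, shape, patch):
        arr = rng.integers(0, 255, size=shape).astype(np.uint8)
        assert np.array_equal(stitch_patches(extract_patches(arr, patch), shape),
                              arr)

    def test_non_positive_patch_dimension_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((4, 4, 4)), (4, 0, 4))

    def test_empty_patchset_rejected(self):
        ps = PatchSet(patches=[], placements=[], pad_record=(0, 0, 0),
                      source_shape=(4, 4, 4), patch_shape=(4, 4, 4))
        with pytest.raises(ValueError):
            stitch_patches(ps, (4, 4, 4))

    def test_out_of_bounds_placement_rejected(self):
        ps = PatchSet(patches=[np.zeros((4, 4, 4))], placements=[(8, 0, 0)],
                      pad_record=(0, 0, 0), source_shape=(4, 4, 4),
                      patch_shape=(4, 4, 4))
        with pytest.raises(ValueError, match="out of bounds"):
            stitch_patches(ps, (4, 4, 4))


class TestNiftiIO:
    def test_header_spacing_passthrough(self, tmp_path):
        path = tmp_path / "vol.nii.gz"
        write_nifti(np.arange(24.0).reshape(2, 3, 4), (1.0, 1.0, 1.0), path)
        vol = read_ct_volume(path)
        assert vol.spacing == (1.0, 1.0, 1.0)
        assert vol.values[1, 2, 3] == 23.0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_ct_volume(tmp_path / "nope.nii")

    def test_non_3d_image_rejected(self, tmp_path):
        path = tmp_path / "vol4d.nii"
        nib.save(nib.Nifti1Image(np.zeros((2, 2, 2, 2)), np.eye(4)), str(path))
        with pytest.raises(ValueError, match="3D"):
            read_ct_volume(path)


class TestResample:
    def test_inplane_resample_changes_only_xy(self, rng):
        arr = rng.normal(size=(20, 24, 5))
        out, spacing = resample_inplane(arr, (10, 12), (1.0, 1.0, 2.5))
        assert out.shape == (10, 12, 5)
        assert spacing == (2.0, 2.0, 2.5)

    def test_label_resample_stays_binary(self, rng):
        lbl = (rng.random(size=(20, 20, 4)) > 0.5).astype(np.uint8)
        out, _ = resample_inplane(lbl, (10, 10), (1, 1, 1), is_label=True)
        assert set(np.unique(out)) <= {0, 1}
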