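"""ROI extraction strategy geometry."""

import numpy as np
import pytest

from osteostage.extract import (
    STRATEGIES,
    extract_lesion_volume,
    extract_patch,
    lesion_slices,
    mask_bbox,
    paste_back,
    sliding_subvolumes,
    sliding_window_starts,
)
from osteostage.types import CtVolume, LesionRecord
from tests.conftest import make_ellipsoid_mask


def test_strategy_registry_covers_all_twelve_plus_primed():
    assert set("ABCDEFGH") <= set(STRATEGIES)
    assert {s + "'" for s in "ABCDEFGH"} <= set(STRATEGIES)
    assert {"I", "J", "K", "L"} <= set(STRATEGIES)
    for sid in "ABCDEFGH":
        assert STRATEGIES[sid].dimensionality == "2.5D" and STRATEGIES[sid].channels == 3
        assert STRATEGIES[sid + "'"].dimensionality == "2D"
    for sid in "IJKL":
        assert STRATEGIES[sid].dimensionality == "3D"


def test_factor_flags_match_strategy_design():
    f = {sid: STRATEGIES[sid].factors for sid in STRATEGIES}
    assert f["A"] == {"morphology"} and f["B"] == {"morphology", "location"}
    assert f["C"] == {"morphology", "texture"}
    assert f["D"] == {"size", "morphology", "texture", "location"}
    assert f["E"] == {"texture"} and f["F"] == {"size", "texture"}
    assert f["G"] == {"size", "texture", "location"} and f["H"] == {"texture"}
    assert f["K"] == {"morphology", "texture"}
    assert f["L"] == {"size", "morphology", "texture"}
    for sid in "ABCDEFGH":
        assert f[sid] == f[sid + "'"]


class TestLesionSlices:
    def test_ellipsoid_span(self):
        m = make_ellipsoid_mask((20, 20, 20), (10, 10, 12), (4, 4, 2.4))
        assert lesion_slices(m) == [10, 11, 12, 13, 14]

    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[3, 3, 5] = True
        assert lesion_slices(m) == [5]

    def test_matches_per_slice_sum_oracle(self, ellipsoid_case):
        _, mask, _ = ellipsoid_case
        oracle = [z for z in range(mask.shape[2]) if mask[:, :, z].sum() > 0]
        assert lesion_slices(mask) == oracle

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            lesion_slices(np.zeros((4, 4, 4), dtype=bool))


class TestPatchStrategies:
    @pytest.fixture(autouse=True)
    def _case(self, ellipsoid_case):
        self.vol, self.mask, self.lesion = ellipsoid_case
        self.z = lesion_slices(self.mask)[len(lesion_slices(self.mask)) // 2]

    def test_mask_strategies_emit_binary_0_255(self):
        for sid in ("A", "B"):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, sid)
            assert set(np.unique(s.pixels)) <= {0, 255}

    def test_masked_strategies_zero_outside_mask(self):
        for sid in ("C", "D", "C'", "D'"):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, sid)
            plane = s.pixels if s.pixels.ndim == 2 else s.pixels[1]
            if STRATEGIES[sid].full_canvas:
                outside = ~self.mask[:, :, self.z]
                assert plane[outside].sum() == 0
            else:
                inside_total = np.where(self.mask[:, :, self.z],
                                        self.vol.voxels[:, :, self.z], 0).sum()
                assert plane.sum() == inside_total

    def test_square_crops_are_square_with_max_bbox_side(self):
        (x0, x1), (y0, y1), _ = mask_bbox(self.mask)
        side = max(x1 - x0, y1 - y0)
        for sid in ("A", "C", "E"):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, sid)
            assert s.pixels.shape[-2:] == (side, side)

    def test_rectangular_crop_matches_tight_bbox(self):
        (x0, x1), (y0, y1), _ = mask_bbox(self.mask)
        s = extract_patch(self.vol, self.mask, self.lesion, self.z, "H")
        assert s.pixels.shape[-2:] == (x1 - x0, y1 - y0)
        np.testing.assert_array_equal(s.pixels[1], self.vol.voxels[x0:x1, y0:y1, self.z])

    def test_fixed_canvas_is_exactly_173(self):
        s = extract_patch(self.vol, self.mask, self.lesion, self.z, "F")
        assert s.pixels.shape[-2:] == (173, 173)

    def test_full_canvas_strategies_keep_volume_shape(self):
        for sid in ("B", "D", "G"):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, sid)
            assert s.pixels.shape[-2:] == self.vol.shape[:2]

    def test_full_canvas_paste_back_recovers_source(self):
        b = extract_patch(self.vol, self.mask, self.lesion, self.z, "B")
        np.testing.assert_array_equal(
            paste_back(b, self.vol.shape[:2]) > 0, self.mask[:, :, self.z]
        )
        d = extract_patch(self.vol, self.mask, self.lesion, self.z, "D")
        np.testing.assert_array_equal(
            paste_back(d, self.vol.shape[:2]),
            np.where(self.mask[:, :, self.z], self.vol.voxels[:, :, self.z], 0),
        )

    def test_cropped_strategies_paste_back_into_source_slice(self):
        for sid in ("E", "H"):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, sid)
            pasted = paste_back(s, self.vol.shape[:2])
            ox, oy = s.meta["origin"]
            h, w = s.pixels.shape[-2:]
            np.testing.assert_array_equal(
                pasted[ox : ox + h, oy : oy + w],
                self.vol.voxels[ox : ox + h, oy : oy + w, self.z],
            )

    def test_g_zeroes_background_outside_window(self):
        s = extract_patch(self.vol, self.mask, self.lesion, self.z, "G", fixed_canvas_px=21)
        plane = s.pixels[1]
        assert plane.shape == self.vol.shape[:2]
        assert (plane > 0).sum() <= 21 * 21
        # inside the window the original image shows through
        nz = np.argwhere(plane > 0)
        for x, y in nz[:10]:
            assert plane[x, y] == self.vol.voxels[x, y, self.z]

    def test_25d_stacks_neighbour_slices_as_channels(self):
        s = extract_patch(self.vol, self.mask, self.lesion, self.z, "E")
        assert s.pixels.shape[0] == 3
        e_prev = extract_patch(self.vol, self.mask, self.lesion, self.z, "E'")
        np.testing.assert_array_equal(s.pixels[1], e_prev.pixels)

    def test_boundary_slice_replicates_edge(self):
        zs = lesion_slices(self.mask)
        vol2 = CtVolume(self.vol.voxels[:, :, zs[0] :], self.vol.spacing_mm, "P", quantized=True)
        mask2 = self.mask[:, :, zs[0] :]
        s = extract_patch(vol2, mask2, self.lesion, 0, "E")
        np.testing.assert_array_equal(s.pixels[0], s.pixels[1])  # z-1 clamped to z

    def test_per_lesion_sample_count_equals_lesion_slices(self):
        zs = lesion_slices(self.mask)
        for sid in "ABCDEFGH":
            samples = [
                extract_patch(self.vol, self.mask, self.lesion, z, sid) for z in zs
            ]
            assert len(samples) == len(zs)

    def test_z_outside_lesion_rejected(self):
        with pytest.raises(ValueError):
            extract_patch(self.vol, self.mask, self.lesion, 0, "C")

    def test_small_fixed_canvas_warns_and_center_crops(self):
        with pytest.warns(RuntimeWarning):
            s = extract_patch(self.vol, self.mask, self.lesion, self.z, "F", fixed_canvas_px=5)
        assert s.pixels.shape[-2:] == (5, 5)


class TestLesionVolumes:
    def test_strategy_i_shape_is_145_by_145_by_full_z(self, ellipsoid_case):
        vol, mask, lesion = ellipsoid_case
        s = extract_lesion_volume(vol, mask, lesion, "I")
        assert s.pixels.shape == (145, 145, vol.shape[2])

    def test_strategy_j_masked_on_tight_bounding_volume(self, ellipsoid_case):
        vol, mask, lesion = ellipsoid_case
        s = extract_lesion_volume(vol, mask, lesion, "J")
        (x0, x1), (y0, y1), (z0, z1) = mask_bbox(mask)
        assert s.pixels.shape == (x1 - x0, y1 - y0, z1 - z0)
        sub = mask[x0:x1, y0:y1, z0:z1]
        assert s.pixels[~sub].sum() == 0

    def test_strategy_l_shape_matches_independent_bbox(self, ellipsoid_case):
        vol, mask, lesion = ellipsoid_case
        s = extract_lesion_volume(vol, mask, lesion, "L")
        idx = np.argwhere(mask)
        expect = tuple(idx.max(axis=0) - idx.min(axis=0) + 1)
        assert s.pixels.shape == expect


class TestSlidingSubvolumes:
    def test_39_slice_extent_yields_17_windows(self):
        assert len(sliding_window_starts(39)) == 17

    def test_extent_7_single_window_weight_1(self):
        m = np.zeros((30, 30, 12), dtype=bool)
        m[10:20, 10:20, 2:9] = True  # z extent exactly 7
        vol = CtVolume(np.ones((30, 30, 12), dtype=np.uint8), (1, 1, 1), "P", quantized=True)
        lesion = LesionRecord("L", "P", "benign", "bone_island", 1)
        windows = sliding_subvolumes(vol, m, lesion, fixed_canvas_px=15)
        assert len(windows) == 1
        assert windows[0].weight == pytest.approx(1.0)

    def test_symmetric_lesion_weight_profile_is_symmetric(self):
        m = make_ellipsoid_mask((40, 40, 21), (20, 20, 10), (8, 8, 7.5))
        vol = CtVolume(np.ones((40, 40, 21), dtype=np.uint8), (1, 1, 1), "P", quantized=True)
        lesion = LesionRecord("L", "P", "benign", "bone_island", 1)
        windows = sliding_subvolumes(vol, m, lesion, fixed_canvas_px=19)
        w = [s.weight for s in windows]
        assert len(w) > 1
        np.testing.assert_allclose(w, w[::-1], rtol=1e-12)

    def test_short_lesion_pads_by_edge_replication(self):
        m = np.zeros((20, 20, 10), dtype=bool)
        m[5:15, 5:15, 4:7] = True  # z extent 3 < 7
        vox = np.zeros((20, 20, 10), dtype=np.uint8)
        vox[:, :, 4] = 50
        vol = CtVolume(vox, (1, 1, 1), "P", quantized=True)
        lesion = LesionRecord("L", "P", "benign", "bone_island", 1)
        (win,) = sliding_subvolumes(vol, m, lesion, fixed_canvas_px=11)
        assert win.pixels.shape[2] == 7
        assert win.weight == pytest.approx(1.0)
        # replicated low-edge slices carry slice-4 content
        assert (win.pixels[:, :, 0] == win.pixels[:, :, 2]).all()

    def test_window_weights_positive_and_sum_positive(self, ellipsoid_case):
        vol, mask, lesion = ellipsoid_case
        windows = sliding_subvolumes(vol, mask, lesion, fixed_canvas_px=21)
        assert all(s.weight > 0 for s in windows)
        assert sum(s.weight for s in windows) > 0
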