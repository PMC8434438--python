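"""Disparity conversion, UV-disparity maps and region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import depthact as da
from depthact import synthetic as syn
from depthact.config import CameraIntrinsics
from depthact.io import DepthFrame
from depthact.roi import (INVALID, DisparityMap, build_region_map,
                          build_uv_disparity, depth_to_disparity,
                          detect_curtain, disparity_pixels, extract_bed,
                          extract_floor, extract_regions, localize_blob,
                          remove_floor)


class TestDisparity:
    def test_pixel_disparity_formula(self):
        intr = CameraIntrinsics(focal_length=320.0, baseline=0.05)
        assert disparity_pixels(2.0, intr) == pytest.approx(8.0)

    def test_inverse_proportionality(self):
        intr = CameraIntrinsics()
        assert disparity_pixels(1.0, intr) == pytest.approx(
            2 * disparity_pixels(2.0, intr))

    def test_constant_depth_single_valued_map(self):
        f = DepthFrame(np.full((6, 6), 2.0))
        dmap = depth_to_disparity(f, CameraIntrinsics())
        assert len(np.unique(dmap.bins)) == 1

    def test_holes_map_to_invalid(self):
        g = np.full((3, 3), 2.0)
        g[1, 1] = 0.0
        dmap = depth_to_disparity(DepthFrame(g), CameraIntrinsics())
        assert dmap.bins[1, 1] == INVALID
        assert dmap.valid.sum() == 8

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(1.0, 8.0), st.floats(1.0, 8.0)))
    def test_order_reversing(self, depths):
        za, zb = depths
        f = DepthFrame(np.array([[za, zb]]))
        dmap = depth_to_disparity(f, CameraIntrinsics())
        a, b = dmap.bins[0]
        if za < zb:
            assert a >= b


class TestUVDisparity:
    def test_constant_map_v_column(self):
        f = DepthFrame(np.full((5, 7), 2.0))
        dmap = depth_to_disparity(f, CameraIntrinsics())
        uv = build_uv_disparity(dmap)
        d = dmap.bins[0, 0]
        assert (uv.v_map[:, d] == 7).all()
        assert (uv.u_map[d, :] == 5).all()

    def test_count_conservation(self, rng):
        g = rng.uniform(1.0, 6.0, (9, 11))
        g[rng.random(g.shape) < 0.2] = 0.0
        dmap = depth_to_disparity(DepthFrame(g), CameraIntrinsics())
        uv = build_uv_disparity(dmap)
        n = dmap.valid.sum()
        assert uv.v_map.sum() == n
        assert uv.u_map.sum() == n

    def test_matches_brute_force_double_loop(self, rng):
        bins = rng.integers(0, 16, size=(8, 8))
        dmap = DisparityMap(bins=bins, n_levels=16)
        uv = build_uv_disparity(dmap)
        v_ref = np.zeros((8, 16), dtype=int)
        u_ref = np.zeros((16, 8), dtype=int)
        for i in range(8):
            for j in range(8):
                v_ref[i, bins[i, j]] += 1
                u_ref[bins[i, j], j] += 1
        np.testing.assert_array_equal(uv.v_map, v_ref)
        np.testing.assert_array_equal(uv.u_map, u_ref)


class TestExtractFloor:
    @pytest.mark.parametrize("tilt", [10.0, 25.0, 40.0])
    def test_closed_loop_against_simulator(self, tilt):
        spec = syn.default_room(noise_sigma=0, hole_rate=0, camera_tilt=tilt)
        depth, regions = syn.render_background(spec)
        f = DepthFrame(depth)
        dmap = depth_to_disparity(f, spec.intrinsics, exclude=depth > 6.0)
        mask, line = extract_floor(build_uv_disparity(dmap), dmap)
        truth = regions == syn.FLOOR
        tp = (mask & truth).sum()
        assert tp / mask.sum() >= 0.9       # precision
        assert tp / truth.sum() >= 0.9      # recall
        assert line is not None

    def test_vertical_wall_yields_empty_mask(self, caplog):
        # constant disparity per column, constant over rows: no slant
        bins = np.full((40, 40), 20)
        dmap = DisparityMap(bins=bins, n_levels=64)
        with caplog.at_level("WARNING"):
            mask, line = extract_floor(build_uv_disparity(dmap), dmap)
        assert not mask.any()
        assert line is None

    def test_line_disparity_increases_toward_image_bottom(self, clean_room):
        spec, depth, _ = clean_room
        dmap = depth_to_disparity(DepthFrame(depth), spec.intrinsics,
                                  exclude=depth > 6.0)
        _, line = extract_floor(build_uv_disparity(dmap), dmap)
        assert line(150) > line(100)


class TestExtractBed:
    def test_closed_loop_iou(self, clean_room):
        spec, depth, regions = clean_room
        dmap = depth_to_disparity(DepthFrame(depth), spec.intrinsics,
                                  exclude=depth > 6.0)
        floor_mask, _ = extract_floor(build_uv_disparity(dmap), dmap)
        bed_mask, ext = extract_bed(remove_floor(dmap, floor_mask))
        truth = regions == syn.BED
        iou = (bed_mask & truth).sum() / (bed_mask | truth).sum()
        assert iou >= 0.7
        assert ext.min_height <= ext.max_height
        assert ext.min_disparity <= ext.max_disparity

    def test_empty_residual_map(self, caplog):
        dmap = DisparityMap(bins=np.full((10, 10), INVALID), n_levels=32)
        with caplog.at_level("WARNING"):
            mask, ext = extract_bed(dmap)
        assert not mask.any()
        assert ext is None

    def test_larger_object_wins(self):
        # two fronto-parallel slabs; the 10x-larger one is chosen as bed
        bins = np.full((60, 60), INVALID)
        bins[5:55, 5:45] = 20    # large slab, disparity 20
        bins[10:20, 50:55] = 40  # small slab, disparity 40
        dmap = DisparityMap(bins=bins, n_levels=64)
        mask, ext = extract_bed(dmap)
        assert ext.min_disparity <= 20 <= ext.max_disparity
        assert not (40 >= ext.min_disparity and 40 <= ext.max_disparity)
        assert mask[30, 30] and not mask[15, 52]


class TestRegionMap:
    def test_all_empty_masks_all_ignored(self):
        rm = build_region_map(np.zeros((4, 4), bool), np.zeros((4, 4), bool))
        assert (rm.labels == syn.IGNORED).all()

    def test_disjoint_masks_copied(self):
        floor = np.zeros((4, 4), bool)
        bed = np.zeros((4, 4), bool)
        floor[0], bed[1] = True, True
        rm = build_region_map(floor, bed)
        assert (rm.labels[0] == syn.FLOOR).all()
        assert (rm.labels[1] == syn.BED).all()
        assert (rm.labels[2:] == syn.IGNORED).all()

    def test_overlap_resolved_floor_first(self):
        m = np.ones((2, 2), bool)
        rm = build_region_map(m, m)
        assert (rm.labels == syn.FLOOR).all()

    def test_full_room_three_region_structure(self, clean_room):
        spec, depth, _ = clean_room
        rm = extract_regions(DepthFrame(depth), spec.intrinsics,
                             far_mask=depth > 6.0)
        present = set(np.unique(rm.labels))
        assert present == {syn.FLOOR, syn.BED, syn.IGNORED}
        # floor dominates the lower image rows, bed is a coherent block
        lower = rm.labels[150:]
        assert (lower == syn.FLOOR).mean() > 0.5


class TestLocalizeBlob:
    def _regions(self):
        labels = np.full((10, 10), syn.IGNORED, dtype=np.int8)
        labels[:, :5] = syn.BED
        labels[:, 5:8] = syn.FLOOR
        return da.RegionMap(labels=labels)

    def test_eighty_percent_on_bed_is_bed(self):
        blob = np.zeros((10, 10), bool)
        blob[0, :5] = True          # 5 px on bed
        blob[1, 8] = True           # 1 px ignored -> 5/6 ~ 83% bed
        assert localize_blob(blob, self._regions()) == "bed"

    def test_bed_test_precedes_floor_test(self):
        # 50% bed (fails 70%), 40% floor (passes 30%) -> floor
        blob = np.zeros((10, 10), bool)
        blob[0, :5] = True      # 5 bed
        blob[0, 5:8] = True     # 3 floor
        blob[1, 5] = True       # 1 floor -> 4/10 on floor
        blob[1, 8] = True       # 1 ignored
        assert localize_blob(blob, self._regions()) == "floor"

    def test_neither_threshold_met_is_other(self):
        blob = np.zeros((10, 10), bool)
        blob[0, 0] = True       # 1 bed
        blob[0, 5] = True       # 1 floor
        blob[:8, 9] = True      # 8 ignored
        assert localize_blob(blob, self._regions()) == "other"

    def test_empty_blob_rejected(self):
        with pytest.raises(ValueError, match="empty blob"):
            localize_blob(np.zeros((4, 4), bool), self._regions())


@pytest.fixture(scope="module")
def curtain_scene():
    spec = syn.default_room(noise_sigma=0, hole_rate=0, curtain=True)
    spec_nc = syn.default_room(noise_sigma=0, hole_rate=0, curtain=False)
    bg_c, _ = syn.render_background(spec)
    bg_nc, _ = syn.render_background(spec_nc)
    return spec, bg_c, bg_nc


class TestDetectCurtain:
    def test_closed_loop_removal(self, curtain_scene):
        spec, bg_c, bg_nc = curtain_scene
        pose = syn.PersonPose(-1.5, 2.2, posture="standing")
        s = syn.render_person(spec, pose.parts())
        person = s < bg_c
        frame = DepthFrame(np.minimum(bg_c, s))
        bgm = da.build_background([DepthFrame(bg_nc)] * 30, 6.0)
        fg = da.subtract_background(frame, bgm)
        dmap = depth_to_disparity(frame, spec.intrinsics,
                                  exclude=bgm.far_mask)
        cmask = detect_curtain(dmap, fg.grid)
        curtain_fg = (bg_c < bg_nc) & ~person & fg.grid
        assert (cmask & curtain_fg).sum() / curtain_fg.sum() >= 0.8
        assert (cmask & person).sum() / person.sum() <= 0.05

    def test_person_only_negative_control(self, curtain_scene):
        spec, _, bg_nc = curtain_scene
        pose = syn.PersonPose(-1.5, 2.2, posture="standing")
        s = syn.render_person(spec, pose.parts())
        frame = DepthFrame(np.minimum(bg_nc, s))
        bgm = da.build_background([DepthFrame(bg_nc)] * 30, 6.0)
        fg = da.subtract_background(frame, bgm)
        dmap = depth_to_disparity(frame, spec.intrinsics,
                                  exclude=bgm.far_mask)
        assert not detect_curtain(dmap, fg.grid).any()

    def test_empty_foreground_empty_mask(self):
        dmap = DisparityMap(bins=np.full((10, 10), 5), n_levels=32)
        assert not detect_curtain(dmap, np.zeros((10, 10), bool)).any()
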