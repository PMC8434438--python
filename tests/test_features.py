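"""Silhouette normalisation, DMA/DMH templates, HOG and floor geometry."""

import numpy as np
import pytest

import depthact as da
from depthact.config import CameraIntrinsics
from depthact.features import (ActionMaps, CANVAS, HOG_LEN,
                               centroid_floor_distance, fit_floor_plane,
                               fuse_features, hog_descriptor,
                               normalize_silhouette, pixel_to_camera,
                               update_dma, update_dmh, update_maps)
from depthact.io import DepthFrame


class TestNormalizeSilhouette:
    def _frame_with_blob(self, r0, c0, h=50, w=30):
        g = np.full((180, 320), 4.0)
        mask = np.zeros((180, 320), bool)
        mask[r0:r0 + h, c0:c0 + w] = True
        g[mask] = 2.0
        return DepthFrame(g), mask

    def test_blob_centred_on_canvas(self):
        frame, mask = self._frame_with_blob(20, 40)
        patch = normalize_silhouette(frame, mask)
        pr, pc = np.nonzero(patch > 0)
        assert abs(pr.mean() - CANVAS[0] / 2) <= 1.0
        assert abs(pc.mean() - CANVAS[1] / 2) <= 1.0

    def test_translation_invariance(self):
        fa, ma = self._frame_with_blob(20, 40)
        fb, mb = self._frame_with_blob(90, 200)
        np.testing.assert_array_equal(normalize_silhouette(fa, ma),
                                      normalize_silhouette(fb, mb))

    def test_canvas_sized_blob_copied_unscaled(self):
        g = np.full((200, 300), 2.0)
        mask = np.zeros((200, 300), bool)
        mask[10:10 + CANVAS[0], 20:20 + CANVAS[1]] = True
        patch = normalize_silhouette(DepthFrame(g), mask)
        assert (patch > 0).sum() == CANVAS[0] * CANVAS[1]

    def test_oversized_blob_downscaled_to_fit(self):
        g = np.full((180, 320), 2.0)
        mask = np.ones((180, 320), bool)  # 180 rows > 176-row canvas
        patch = normalize_silhouette(DepthFrame(g), mask)
        assert patch.shape == CANVAS
        assert (patch > 0).any()

    def test_empty_blob_rejected(self):
        with pytest.raises(ValueError, match="empty blob"):
            normalize_silhouette(DepthFrame(np.ones((10, 10))),
                                 np.zeros((10, 10), bool))


def _batch_dma_dmh(patches, tau, delta):
    """Independent batch oracle: recompute both maps from definitions."""
    shape = patches[0].shape
    dma = np.zeros(shape)
    dmh = np.zeros(shape)
    prev = np.zeros(shape)
    for p in patches:
        for i in range(shape[0]):
            for j in range(shape[1]):
                if p[i, j] > 0:
                    dma[i, j] = p[i, j] if dma[i, j] == 0 \
                        else min(dma[i, j], p[i, j])
                if abs(p[i, j] - prev[i, j]) > delta:
                    dmh[i, j] = tau
                else:
                    dmh[i, j] = max(dmh[i, j] - 1, 0)
        prev = p
    return dma, dmh


class TestActionMaps:
    def test_first_patch_becomes_dma(self):
        maps = ActionMaps(shape=(4, 4))
        p = np.full((4, 4), 2.0)
        update_dma(maps, p)
        np.testing.assert_array_equal(maps.dma, p)

    def test_minimum_branch(self):
        maps = ActionMaps(shape=(1, 1))
        update_dma(maps, np.array([[2.0]]))
        update_dma(maps, np.array([[1.5]]))
        assert maps.dma[0, 0] == 1.5

    def test_repeated_patch_idempotent(self):
        maps = ActionMaps(shape=(3, 3))
        p = np.full((3, 3), 2.5)
        for _ in range(5):
            update_dma(maps, p)
        np.testing.assert_array_equal(maps.dma, p)

    def test_zero_padding_does_not_erase_dma(self):
        maps = ActionMaps(shape=(2, 2))
        update_dma(maps, np.full((2, 2), 2.0))
        update_dma(maps, np.zeros((2, 2)))
        np.testing.assert_array_equal(maps.dma, 2.0)

    def test_dmh_motion_then_decay(self):
        maps = ActionMaps(tau=30, delta=0.01, shape=(1, 1))
        update_dmh(maps, np.array([[2.02]]), np.array([[2.0]]))
        assert maps.dmh[0, 0] == 30
        update_dmh(maps, np.array([[2.02]]), np.array([[2.02]]))
        assert maps.dmh[0, 0] == 29

    def test_static_pixel_stays_zero(self):
        maps = ActionMaps(shape=(2, 2))
        p = np.full((2, 2), 3.0)
        for _ in range(4):
            update_dmh(maps, p, p)
        assert (maps.dmh == 0).all()

    def test_dmh_range_invariant(self, rng):
        maps = ActionMaps(tau=10, delta=0.01, shape=(8, 8))
        prev = rng.uniform(1, 3, (8, 8))
        for _ in range(25):
            cur = rng.uniform(1, 3, (8, 8))
            update_dmh(maps, cur, prev)
            prev = cur
            assert (maps.dmh >= 0).all() and (maps.dmh <= 10).all()

    def test_incremental_equals_batch_oracle(self, rng):
        for trial in range(10):
            patches = [np.where(rng.random((16, 16)) < 0.7,
                                rng.uniform(1, 3, (16, 16)), 0.0)
                       for _ in range(10)]
            maps = ActionMaps(tau=30, delta=0.01, shape=(16, 16))
            prev = None
            for p in patches:
                update_maps(maps, p, prev)
                prev = p
            dma_ref, dmh_ref = _batch_dma_dmh(patches, 30, 0.01)
            np.testing.assert_array_equal(maps.dma, dma_ref)
            np.testing.assert_array_equal(maps.dmh, dmh_ref)

    def test_shape_mismatch_rejected(self):
        maps = ActionMaps(shape=(4, 4))
        with pytest.raises(ValueError):
            update_dma(maps, np.ones((3, 3)))


def _hog_oracle(grid, cell=16, bins=9, eps=1e-6):
    """Independent per-cell histogram + normalisation oracle."""
    H, W = grid.shape
    gx = np.zeros_like(grid)
    gy = np.zeros_like(grid)
    gx[:, 1:-1] = (grid[:, 2:] - grid[:, :-2]) / 2
    gx[:, 0] = grid[:, 1] - grid[:, 0]
    gx[:, -1] = grid[:, -1] - grid[:, -2]
    gy[1:-1, :] = (grid[2:, :] - grid[:-2, :]) / 2
    gy[0, :] = grid[1, :] - grid[0, :]
    gy[-1, :] = grid[-1, :] - grid[-2, :]
    out = []
    for cr in range(H // cell):
        for cc in range(W // cell):
            hist = np.zeros(bins)
            for i in range(cr * cell, (cr + 1) * cell):
                for j in range(cc * cell, (cc + 1) * cell):
                    m = np.hypot(gx[i, j], gy[i, j])
                    a = np.degrees(np.arctan2(gy[i, j], gx[i, j])) % 180.0
                    hist[min(int(a / 20.0), bins - 1)] += m
            out.append(hist / np.sqrt((hist ** 2).sum() + eps ** 2))
    return np.concatenate(out)


class TestHog:
    def test_descriptor_length_1584(self, rng):
        assert hog_descriptor(rng.random(CANVAS)).shape == (HOG_LEN,)
        assert HOG_LEN == 16 * 11 * 9

    def test_constant_map_zero_descriptor(self):
        assert not hog_descriptor(np.full(CANVAS, 2.0)).any()

    def test_vertical_step_edge_energy_in_horizontal_gradient_bin(self):
        g = np.zeros(CANVAS)
        g[:, 128:] = 3.0  # vertical edge at a cell boundary region
        desc = hog_descriptor(g).reshape(11, 16, 9)
        edge_cells = desc[:, 7:9, :]
        # gradient points along +x -> orientation 0 -> first bin
        assert edge_cells[..., 0].sum() > 0.9 * edge_cells.sum()

    def test_matches_brute_force_oracle(self, rng):
        g = rng.uniform(0, 3, (32, 48))
        np.testing.assert_allclose(hog_descriptor(g), _hog_oracle(g),
                                   atol=1e-6)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            hog_descriptor(np.ones((100, 100)))


class TestFuseFeatures:
    def test_length_and_order(self, rng):
        a, b = rng.random(HOG_LEN), rng.random(HOG_LEN)
        fused = fuse_features(a, b)
        assert fused.shape == (2 * HOG_LEN,)
        np.testing.assert_array_equal(fused[:HOG_LEN], a)
        np.testing.assert_array_equal(fused[HOG_LEN:], b)

    def test_zero_plus_zero(self):
        assert not fuse_features(np.zeros(HOG_LEN), np.zeros(HOG_LEN)).any()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_features(np.zeros(HOG_LEN), np.zeros(HOG_LEN - 1))


class TestFloorPlane:
    def test_axis_aligned_exact_fit(self, rng):
        xy = rng.uniform(-2, 2, (50, 2))
        pts = np.column_stack([xy, np.full(50, 2.0)])
        plane = fit_floor_plane(pts)
        np.testing.assert_allclose(np.abs(plane.coefficients),
                                   [0, 0, 1, 2], atol=1e-9)

    def test_noisy_tilted_plane_recovery(self, rng):
        normal = np.array([0.1, 0.9, 0.4])
        normal /= np.linalg.norm(normal)
        d = -1.7
        basis = np.linalg.svd(normal[None])[2][1:]
        uv = rng.uniform(-2, 2, (500, 2))
        pts = (-d) * normal + uv @ basis + \
            rng.normal(0, 0.01, (500, 1)) * normal
        plane = fit_floor_plane(pts)
        cosang = abs(plane.coefficients[:3] @ normal)
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 1.0
        assert abs(abs(plane.d) - abs(d)) < 0.02

    def test_three_points_interpolating(self):
        pts = np.array([[0, 0, 1.0], [1, 0, 2.0], [0, 1, 3.0]])
        plane = fit_floor_plane(pts)
        res = pts @ plane.coefficients[:3] + plane.d
        np.testing.assert_allclose(res, 0, atol=1e-12)

    def test_collinear_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_floor_plane(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_floor_plane(np.array([[0, 0, 0], [1, 0, 0.0]]))


class TestPixelToCamera:
    def test_principal_point_maps_to_axis(self):
        intr = CameraIntrinsics()
        X, Y, Z = pixel_to_camera(*intr.principal_point, 2.0, intr)
        assert X == 0 and Y == 0 and Z == 2.0

    def test_one_focal_length_off_axis(self):
        intr = CameraIntrinsics()
        cx, cy = intr.principal_point
        X, _, _ = pixel_to_camera(cx + intr.focal_length, cy, 2.0, intr)
        assert X == pytest.approx(2.0)

    def test_linear_in_depth(self):
        intr = CameraIntrinsics()
        X1, Y1, _ = pixel_to_camera(200, 120, 1.5, intr)
        X2, Y2, _ = pixel_to_camera(200, 120, 3.0, intr)
        assert X2 == pytest.approx(2 * X1) and Y2 == pytest.approx(2 * Y1)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            pixel_to_camera(10, 10, 0.0, CameraIntrinsics())


class TestCentroidFloorDistance:
    def test_point_on_plane_zero(self):
        plane = da.FloorPlane(0.0, 0.0, 1.0, -2.0)
        assert centroid_floor_distance((5.0, 5.0, 2.0), plane) == 0.0

    def test_axis_offset_case(self):
        plane = da.FloorPlane(0.0, 0.0, 1.0, 0.0)
        assert centroid_floor_distance((0.0, 0.0, 1.5), plane) == 1.5

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if n[2] < 0:
                n = -n
            d = rng.uniform(-3, 3)
            p = rng.uniform(-3, 3, 3)
            plane = da.FloorPlane(*n, d)
            got = centroid_floor_distance(tuple(p), plane)
            assert abs(got) == pytest.approx(abs(n @ p + d), abs=1e-12)

    def test_positive_above_floor_for_camera_plane(self):
        # downward-tilted camera: floor plane has d = -camera_height < 0
        import math
        t = math.radians(25)
        plane = da.FloorPlane(0.0, math.cos(t), math.sin(t), -2.1)
        # the camera origin is 2.1 m above the floor
        assert centroid_floor_distance((0, 0, 0), plane) == \
            pytest.approx(2.1)
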