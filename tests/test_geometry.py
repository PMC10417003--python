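import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigcloud import (
    BoxMask,
    CameraIntrinsics,
    InstanceMaskSet,
    backproject_pixel,
    build_instance_masks,
    depth_to_cloud,
    extract_object_clouds,
    project_point,
)
from pigcloud.errors import (
    AnnotationError,
    InvalidDepthError,
    RegistrationMismatchError,
)

from oracles import backproject_loop


class TestBackprojection:
    def test_principal_point_ray(self, test_cam):
        assert backproject_pixel(test_cam.cx, test_cam.cy, 1000, test_cam) == (0.0, 0.0, 1.0)

    def test_unit_tangent(self, test_cam):
        x, y, z = backproject_pixel(test_cam.cx + test_cam.fx, test_cam.cy, 2000, test_cam)
        assert (x, y, z) == (2.0, 0.0, 2.0)

    def test_zero_depth_rejected(self, test_cam):
        with pytest.raises(InvalidDepthError):
            backproject_pixel(10, 10, 0, test_cam)

    def test_out_of_frame_rejected(self, test_cam):
        with pytest.raises(ValueError):
            backproject_pixel(test_cam.width, 0, 100, test_cam)

    def test_roundtrip_reprojection_grid(self, test_cam, rng):
        """Back-projecting then projecting recovers the pixel to < 1e-9 px."""
        us = rng.uniform(0, test_cam.width - 1e-6, 100)
        vs = rng.uniform(0, test_cam.height - 1e-6, 100)
        ds = rng.integers(1, 6000, 100)
        worst = 0.0
        for u, v, d in zip(us, vs, ds):
            x, y, z = backproject_pixel(u, v, int(d), test_cam)
            uu, vv = project_point(x, y, z, test_cam)
            worst = max(worst, abs(uu - u), abs(vv - v))
        assert worst < 1e-9

    @settings(derandomize=True, max_examples=50)
    @given(
        u=st.floats(0, 319), v=st.floats(0, 239),
        d=st.integers(1, 65535),
    )
    def test_depth_equals_scaled_count(self, u, v, d):
        cam = CameraIntrinsics(fx=100.0, fy=100.0, cx=160.0, cy=120.0, width=320, height=240)
        _, _, z = backproject_pixel(u, v, d, cam)
        assert z == d * cam.depth_scale


class TestDepthToCloud:
    def test_all_zero_depth_empty_cloud(self, tiny_cam):
        rgb = np.zeros((8, 8, 3), np.uint8)
        cloud = depth_to_cloud(rgb, np.zeros((8, 8), np.uint16), tiny_cam)
        assert len(cloud) == 0

    def test_constant_depth_full_frame(self, tiny_cam):
        rgb = np.zeros((8, 8, 3), np.uint8)
        depth = np.full((8, 8), 3000, np.uint16)
        cloud = depth_to_cloud(rgb, depth, tiny_cam)
        assert len(cloud) == 64
        assert np.allclose(cloud.points[:, 2], 3.0)

    def test_shape_mismatch_signalled(self, tiny_cam):
        with pytest.raises(RegistrationMismatchError):
            depth_to_cloud(np.zeros((8, 9, 3), np.uint8), np.zeros((8, 8), np.uint16), tiny_cam)

    def test_matches_bruteforce_loop(self, small_scene):
        fx = small_scene
        cloud = depth_to_cloud(fx.rgb, fx.depth, fx.config.intrinsics)
        pts, cols = backproject_loop(fx.rgb, fx.depth, fx.config.intrinsics)
        assert np.array_equal(cloud.points, pts)
        assert np.array_equal(cloud.colors, cols)

    def test_point_count_ignores_rgb(self, clean_scene, rng):
        fx = clean_scene
        other_rgb = rng.integers(0, 256, fx.rgb.shape, np.uint8)
        a = depth_to_cloud(fx.rgb, fx.depth, fx.config.intrinsics)
        b = depth_to_cloud(other_rgb, fx.depth, fx.config.intrinsics)
        assert len(a) == len(b)
        assert np.array_equal(a.points, b.points)

    def test_depth_scale_invariance(self, tiny_cam, rng):
        """Scaling counts by k and depth_scale by 1/k leaves the cloud unchanged."""
        rgb = np.zeros((8, 8, 3), np.uint8)
        depth = rng.integers(0, 5000, (8, 8)).astype(np.uint16)
        k = 4
        scaled_cam = CameraIntrinsics(
            fx=tiny_cam.fx, fy=tiny_cam.fy, cx=tiny_cam.cx, cy=tiny_cam.cy,
            width=8, height=8, depth_scale=tiny_cam.depth_scale / k,
        )
        a = depth_to_cloud(rgb, depth, tiny_cam)
        b = depth_to_cloud(rgb, (depth.astype(np.uint32) * k).astype(np.uint32), scaled_cam)
        assert np.allclose(a.points, b.points)


class TestBuildInstanceMasks:
    def test_single_box_intersects_blob(self):
        semantic = np.zeros((20, 20), bool)
        semantic[5:10, 5:7] = True  # 10-pixel blob
        masks = build_instance_masks(
            [BoxMask(box=(0, 0, 20, 20), score=0.99)], semantic, [(255, 0, 0)]
        )
        assert masks.instance_mask(0).sum() == 10

    def test_blob_outside_boxes_yields_black_mask(self):
        semantic = np.zeros((20, 20), bool)
        semantic[15:19, 15:19] = True
        masks = build_instance_masks(
            [BoxMask(box=(0, 0, 5, 5), score=0.9)], semantic, [(255, 0, 0)]
        )
        assert not masks.mask_image.any()

    def test_overlap_goes_to_higher_score(self):
        semantic = np.ones((10, 10), bool)
        boxes = [
            BoxMask(box=(0, 0, 6, 10), score=0.95),
            BoxMask(box=(4, 0, 10, 10), score=0.90),
        ]
        colours = [(255, 0, 0), (0, 255, 0)]
        masks = build_instance_masks(boxes, semantic, colours)
        overlap = masks.mask_image[:, 4:6]
        assert np.all(overlap == np.array([255, 0, 0], np.uint8))
        # Exhaustive per-pixel check of the assignment rule.
        for v in range(10):
            for u in range(10):
                px = tuple(masks.mask_image[v, u])
                if u < 4:
                    assert px == (255, 0, 0)
                elif u < 6:
                    assert px == (255, 0, 0)  # contested: higher score wins
                else:
                    assert px == (0, 255, 0)

    def test_score_tie_goes_to_lower_index(self):
        semantic = np.ones((4, 4), bool)
        boxes = [BoxMask(box=(0, 0, 4, 4), score=0.9), BoxMask(box=(0, 0, 4, 4), score=0.9)]
        masks = build_instance_masks(boxes, semantic, [(255, 0, 0), (0, 255, 0)])
        assert np.all(masks.mask_image == np.array([255, 0, 0], np.uint8))

    def test_too_few_colours_rejected(self):
        with pytest.raises(AnnotationError):
            build_instance_masks(
                [BoxMask(box=(0, 0, 2, 2)), BoxMask(box=(2, 2, 4, 4))],
                np.ones((4, 4), bool),
                [(255, 0, 0)],
            )


class TestExtractObjectClouds:
    def test_empty_mask_gives_empty_clouds_per_colour(self, tiny_cam):
        rgb = np.zeros((8, 8, 3), np.uint8)
        depth = np.full((8, 8), 2000, np.uint16)
        masks = InstanceMaskSet(
            mask_image=np.zeros((8, 8, 3), np.uint8),
            colour_list=[(255, 0, 0), (0, 255, 0)],
        )
        clouds = extract_object_clouds(rgb, depth, masks, tiny_cam)
        assert [len(c) for c in clouds] == [0, 0]

    def test_counts_match_bruteforce_mask_depth_loop(self, small_noisy_scene):
        fx = small_noisy_scene
        clouds = extract_object_clouds(fx.rgb, fx.depth, fx.masks, fx.config.intrinsics)
        for i, cloud in enumerate(clouds):
            select = fx.masks.instance_mask(i)
            pts, cols = backproject_loop(fx.rgb, fx.depth, fx.config.intrinsics, select)
            assert np.array_equal(cloud.points, pts)
            assert np.array_equal(cloud.colors, cols)

    def test_object_clouds_subset_of_full_cloud(self, clean_scene):
        fx = clean_scene
        full = depth_to_cloud(fx.rgb, fx.depth, fx.config.intrinsics)
        full_set = {tuple(p) for p in full.points}
        for cloud in extract_object_clouds(fx.rgb, fx.depth, fx.masks, fx.config.intrinsics):
            assert {tuple(p) for p in cloud.points} <= full_set

    def test_partition_property(self, small_scene):
        """Non-overlapping masks: union of object clouds = masked subset of full cloud."""
        fx = small_scene
        intr = fx.config.intrinsics
        clouds = extract_object_clouds(fx.rgb, fx.depth, fx.masks, intr)
        union = np.vstack([c.points for c in clouds])
        any_mask = np.any(fx.masks.mask_image != 0, axis=2)
        expected, _ = backproject_loop(fx.rgb, fx.depth, intr, any_mask)
        assert sorted(map(tuple, union)) == sorted(map(tuple, expected))

    def test_no_zero_depth_points(self, clean_scene):
        fx = clean_scene
        depth = fx.depth.copy()
        mask0 = fx.masks.instance_mask(0)
        vv, uu = np.nonzero(mask0)
        depth[vv[:50], uu[:50]] = 0  # knock out 50 returns inside instance 0
        clouds = extract_object_clouds(fx.rgb, depth, fx.masks, fx.config.intrinsics)
        assert len(clouds[0]) == mask0.sum() - 50
        for c in clouds:
            assert np.all(c.points[:, 2] > 0)

    def test_unlisted_colour_signalled(self, tiny_cam):
        mask_image = np.zeros((8, 8, 3), np.uint8)
        mask_image[0, 0] = (12, 34, 56)
        masks = InstanceMaskSet(mask_image=mask_image, colour_list=[(255, 0, 0)])
        with pytest.raises(AnnotationError):
            extract_object_clouds(
                np.zeros((8, 8, 3), np.uint8), np.full((8, 8), 1000, np.uint16),
                masks, tiny_cam,
            )
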