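"""Skeleton morphometry: thresholding, dilation, thinning, length measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromodisp.morphometry import (
    PipelineConfig,
    ProjectedImage,
    binarize,
    dilate,
    intermeans_threshold,
    max_project,
    measure_skeleton,
    skeleton_dot_length_pipeline,
    skeletonize,
    total_skeleton_length,
)
from chromodisp.synthetic import SyntheticSceneParams, generate_fish_scene

from oracles import brute_dilate, brute_max_project, pixel_graph_lengths

SQRT2 = math.sqrt(2.0)


class TestMaxProject:
    def test_single_plane_is_identity(self):
        plane = np.arange(12.0).reshape(3, 4)
        out = max_project(plane[None], 0.1)
        assert np.array_equal(out.pixels, plane)

    def test_zero_plane_is_absorbed(self):
        plane = np.arange(12.0).reshape(3, 4)
        stack = np.stack([plane, np.zeros_like(plane)])
        assert np.array_equal(max_project(stack, 0.1).pixels, plane)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        stack = rng.random((3, 8, 8))
        assert np.array_equal(max_project(stack, 0.1).pixels, brute_max_project(stack))

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)), 0.1)


class TestBinarize:
    def test_two_valued_image_splits_on_values(self):
        img = np.zeros((10, 10))
        img[3:6, 3:6] = 1000.0
        res = binarize(ProjectedImage(img, 0.1))
        assert np.array_equal(res.mask, img == 1000.0)

    def test_fixed_zero_keeps_strictly_positive(self):
        img = np.array([[0.0, 0.5], [2.0, 0.0]])
        res = binarize(ProjectedImage(img, 0.1), method="fixed:0")
        assert np.array_equal(res.mask, img > 0)

    def test_isodata_is_intermeans_fixed_point(self):
        """The auto threshold must be a fixed point of the independent
        intermeans iteration t = (mean_below + mean_above)/2."""
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0.1, 0.02, 3000), rng.normal(0.8, 0.05, 500)])
        img = np.clip(values, 0, 1).reshape(50, 70)
        t = binarize(ProjectedImage(img, 0.1)).threshold
        below, above = img[img < t], img[img >= t]
        assert t == pytest.approx(0.5 * (below.mean() + above.mean()), abs=1e-6)
        assert 0.2 < t < 0.7  # separates the two planted modes

    def test_constant_image_directs_to_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            binarize(ProjectedImage(np.full((5, 5), 0.3), 0.1))


class TestDilate:
    def test_single_pixel_three_iterations_fills_7x7(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        out = dilate(m, 3)
        expected = np.zeros((9, 9), bool)
        expected[1:8, 1:8] = True
        assert np.array_equal(out, expected)

    def test_saturated_mask_unchanged(self):
        m = np.ones((6, 6), bool)
        assert np.array_equal(dilate(m, 3), m)

    def test_matches_neighborhood_or_oracle(self):
        rng = np.random.default_rng(11)
        m = rng.random((16, 16)) < 0.2
        assert np.array_equal(dilate(m, 3), brute_dilate(m, 3))

    def test_negative_iterations_error(self):
        with pytest.raises(ValueError):
            dilate(np.zeros((3, 3), bool), -1)

    def test_foreground_never_shrinks(self):
        rng = np.random.default_rng(2)
        m = rng.random((20, 20)) < 0.1
        assert np.all(dilate(m, 1) | ~m)


class TestSkeletonize:
    def test_ribbon_thins_to_width_one_path(self):
        m = np.zeros((7, 20), bool)
        m[2:5, 2:18] = True
        sk = skeletonize(m)
        assert sk.sum() > 0 and np.all(m | ~sk)  # skeleton subset of mask
        # width-1: no pixel has a full 3x3 neighborhood
        from scipy import ndimage

        full = ndimage.uniform_filter(sk.astype(float), 3) >= 1.0 - 1e-9
        assert not np.any(full & sk)

    def test_single_pixel_preserved(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert np.array_equal(skeletonize(m), m)

    def test_square_connectivity_and_width(self):
        from scipy import ndimage

        m = np.zeros((11, 11), bool)
        m[2:9, 2:9] = True
        sk = skeletonize(m)
        _, n_mask = ndimage.label(m, structure=np.ones((3, 3)))
        _, n_skel = ndimage.label(sk, structure=np.ones((3, 3)))
        assert n_skel == n_mask == 1
        full = ndimage.uniform_filter(sk.astype(float), 3) >= 1.0 - 1e-9
        assert not np.any(full & sk)

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((4, 4), bool)).any()


class TestMeasureSkeleton:
    def test_horizontal_run(self):
        sk = np.zeros((5, 15), bool)
        sk[2, 2:13] = True
        (m,) = measure_skeleton(sk, sk, 0.1)
        assert m.skeleton_dot_length_um == pytest.approx(1.0)
        assert m.n_branches == 1

    def test_single_pixel_zero_length_zero_branches(self):
        sk = np.zeros((5, 5), bool)
        sk[2, 2] = True
        (m,) = measure_skeleton(sk, sk, 0.1)
        assert m.skeleton_dot_length_um == 0.0
        assert m.n_branches == 0

    def test_diagonal_run(self):
        sk = np.zeros((12, 12), bool)
        for i in range(8):
            sk[1 + i, 1 + i] = True
        (m,) = measure_skeleton(sk, sk, 0.1)
        assert m.skeleton_dot_length_um == pytest.approx(7 * SQRT2 * 0.1)

    def test_y_junction_three_branches(self):
        sk = np.zeros((11, 11), bool)
        sk[5, 1:6] = True
        for i in range(1, 5):
            sk[5 - i, 5 + i] = True
            sk[5 + i, 5 + i] = True
        (m,) = measure_skeleton(sk, sk, 0.1)
        assert m.n_branches == 3
        assert m.skeleton_dot_length_um == pytest.approx((4 + 8 * SQRT2) * 0.1)

    def test_fragments_sum_within_one_focus(self):
        """Two skeleton fragments inside one dilated component give one
        focus with the summed length."""
        source = np.zeros((9, 20), bool)
        source[2:7, 1:19] = True
        sk = np.zeros((9, 20), bool)
        sk[4, 2:7] = True
        sk[4, 12:18] = True
        (m,) = measure_skeleton(sk, source, 0.1)
        assert m.skeleton_dot_length_um == pytest.approx((4 + 5) * 0.1)
        assert m.n_branches == 2

    def test_invalid_pixel_size_errors(self):
        sk = np.zeros((3, 3), bool)
        with pytest.raises(ValueError):
            measure_skeleton(sk, sk, 0.0)

    def test_rotation_invariance(self, small_mask_fixture_set):
        """90-degree rotation leaves the length multiset unchanged."""
        for mask in small_mask_fixture_set[::10]:
            sk = skeletonize(mask)
            a = sorted(
                m.skeleton_dot_length_um for m in measure_skeleton(sk, mask, 0.1)
            )
            rot_mask = np.rot90(mask).copy()
            rot_sk = np.rot90(sk).copy()
            b = sorted(
                m.skeleton_dot_length_um
                for m in measure_skeleton(rot_sk, rot_mask, 0.1)
            )
            assert a == pytest.approx(b, abs=1e-9)

    @given(scale=st.sampled_from([0.5, 1.0, 2.0, 3.7]))
    @settings(deadline=None, derandomize=True)
    def test_calibration_linearity(self, scale):
        sk = np.zeros((9, 9), bool)
        sk[4, 1:8] = True
        sk[1:4, 4] = True
        (m1,) = measure_skeleton(sk, sk, 0.1)
        (m2,) = measure_skeleton(sk, sk, 0.1 * scale)
        assert m2.skeleton_dot_length_um == pytest.approx(m1.skeleton_dot_length_um * scale)


class TestPipeline:
    def test_compact_scene_yields_one_small_focus(self):
        scene = generate_fish_scene(
            SyntheticSceneParams(n_nuclei=1, foci_per_nucleus=1,
                                 subpuncta_per_focus=1, focus_spread_um=0.0, seed=3)
        )
        ms = skeleton_dot_length_pipeline(ProjectedImage(scene.image, scene.pixel_size_um))
        assert len(ms) == 1
        assert ms[0].skeleton_dot_length_um < 0.75  # below the compact cutoff

    def test_empty_image_gives_empty_list(self):
        ms = skeleton_dot_length_pipeline(ProjectedImage(np.zeros((64, 64)), 0.1))
        assert ms == []

    def test_two_separated_blobs_give_two_foci(self):
        scene = generate_fish_scene(
            SyntheticSceneParams(n_nuclei=2, foci_per_nucleus=1,
                                 subpuncta_per_focus=1, focus_spread_um=0.0, seed=5)
        )
        ms = skeleton_dot_length_pipeline(ProjectedImage(scene.image, scene.pixel_size_um))
        assert len(ms) == len(scene.truth["foci"]) == 2

    def test_ordering_is_row_major_and_intermediates_consistent(self):
        scene = generate_fish_scene(SyntheticSceneParams(seed=9))
        ms, inter = skeleton_dot_length_pipeline(
            ProjectedImage(scene.image, scene.pixel_size_um),
            PipelineConfig(keep_intermediates=True),
        )
        rows = [m.centroid_px for m in ms]
        assert rows == sorted(rows)
        assert np.all(inter["dilated"] | ~inter["binary"])
        assert np.all(inter["dilated"] | ~inter["skeleton"])
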