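import math

import numpy as np
import pytest

from gliaquant import phantom as ph
from gliaquant import quantify as qt
from gliaquant.segment import BinaryMask
from gliaquant.volume_io import VolumetricImage
from gliaquant.quantify import (
    compute_edm_thickness,
    compute_surface,
    compute_volume_coverage,
    quantify_stack,
    skeleton_statistics,
    skeletonize_3d,
    write_quantification_csvs,
)


class TestVolumeCoverage:
    def test_full_mask(self):
        mask = BinaryMask(np.ones((3, 4, 5), np.uint8), (0.5, 0.5, 1.0))
        v, cov, n = compute_volume_coverage(mask)
        assert cov == 100.0
        assert v == pytest.approx(3 * 4 * 5 * 0.25)
        assert n == 1

    def test_empty_mask(self):
        mask = BinaryMask(np.zeros((3, 4, 5), np.uint8), (1, 1, 1))
        assert compute_volume_coverage(mask) == (0.0, 0.0, 0)

    def test_cylinder_volume_vs_analytic(self):
        # r = 10 vox = 5 um, h = 50 vox = 25 um at 0.5 um iso
        mask = ph.make_cylinder_mask((26, 60, 26), (0.5, 0.5, 0.5),
                                     radius_um=5.0, height_um=25.0, axis="y")
        v, _, n = compute_volume_coverage(mask)
        assert n == 1
        assert v == pytest.approx(math.pi * 25 * 25, rel=0.05)

    def test_object_count(self):
        vox = np.zeros((5, 10, 10), np.uint8)
        vox[1, 1, 1] = 1
        vox[3, 7:9, 7:9] = 1
        assert compute_volume_coverage(BinaryMask(vox, (1, 1, 1)))[2] == 2


class TestSurface:
    def test_single_voxel_all_surface(self):
        vox = np.zeros((3, 3, 3), np.uint8)
        vox[1, 1, 1] = 1
        s_um3, sv, _ = compute_surface(BinaryMask(vox, (1, 1, 1)))
        assert sv == 1.0
        assert s_um3 == 1.0

    def test_cube_surface_count_oracle(self):
        vox = np.zeros((12, 12, 12), np.uint8)
        vox[1:11, 1:11, 1:11] = 1
        mask = BinaryMask(vox, (1, 1, 1))
        s_um3, sv, _ = compute_surface(mask)
        # brute-force neighbor scan
        count = 0
        for z in range(12):
            for y in range(12):
                for x in range(12):
                    if not vox[z, y, x]:
                        continue
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if not (0 <= zz < 12 and 0 <= yy < 12 and 0 <= xx < 12) \
                                or not vox[zz, yy, xx]:
                            count += 1
                            break
        assert count == 10**3 - 8**3 == 488
        assert s_um3 == float(count)
        assert sv == count / 1000

    def test_thin_sheet_all_surface(self):
        vox = np.zeros((5, 8, 8), np.uint8)
        vox[2] = 1
        assert compute_surface(BinaryMask(vox, (1, 1, 1)))[1] == 1.0

    def test_border_voxels_are_surface(self):
        vox = np.ones((4, 4, 4), np.uint8)
        s_um3, sv, _ = compute_surface(BinaryMask(vox, (1, 1, 1)))
        assert sv == pytest.approx((64 - 8) / 64)

    def test_surface_leq_volume(self, rng):
        vox = (rng.random((6, 10, 10)) > 0.5).astype(np.uint8)
        mask = BinaryMask(vox, (1, 1, 1))
        s_um3, sv, _ = compute_surface(mask)
        assert s_um3 <= compute_volume_coverage(mask)[0]
        assert 0.0 <= sv <= 1.0


class TestEdmThickness:
    def test_half_space_closed_form(self):
        vox = np.zeros((4, 20, 6), np.uint8)
        vox[:, :10, :] = 1
        edm, _, _ = compute_edm_thickness(
            BinaryMask(vox, (1.0, 0.5, 1.0)),
            skeleton=skeletonize_3d(BinaryMask(vox, (1.0, 0.5, 1.0))))
        # interior columns: distance to the y-boundary at dy = 0.5
        for depth in range(1, 8):
            row = 10 - depth
            assert edm[1, row, 3] == pytest.approx(depth * 0.5)

    def test_cylinder_thickness_within_one_voxel(self, cylinder_mask,
                                                 cylinder_skeleton):
        _, t_mean, _ = compute_edm_thickness(cylinder_mask, cylinder_skeleton)
        assert abs(t_mean - 2.5) <= 0.5  # 1 voxel at 0.5 um

    def test_single_voxel_object(self):
        vox = np.zeros((3, 3, 3), np.uint8)
        vox[1, 1, 1] = 1
        mask = BinaryMask(vox, (0.5, 0.7, 1.0))
        edm, t_mean, _ = compute_edm_thickness(mask, skeletonize_3d(mask))
        assert edm[1, 1, 1] <= min(0.5, 0.7, 1.0) + 1e-9
        assert t_mean == pytest.approx(edm[1, 1, 1])

    def test_thickness_leq_max_edm(self, cylinder_mask, cylinder_skeleton):
        edm, t_mean, t_max = compute_edm_thickness(cylinder_mask,
                                                   cylinder_skeleton)
        assert t_mean <= edm.max() + 1e-12
        assert t_max <= edm.max() + 1e-12

    def test_cylinder_thickness_converges_with_resolution(self):
        # the centerline-sampled EDM error is bounded by the voxel pitch,
        # so halving the pitch halves the attainable error bound
        for voxel in (1.0, 0.5):
            mask = ph.make_cylinder_mask(
                (int(12 / voxel) + 1, int(20 / voxel), int(12 / voxel) + 1),
                (voxel, voxel, voxel), radius_um=4.0, height_um=14.0)
            _, t_mean, _ = compute_edm_thickness(mask, skeletonize_3d(mask))
            assert abs(t_mean - 4.0) <= voxel


class TestSkeletonize:
    def test_cylinder_is_single_path(self, cylinder_mask, cylinder_skeleton):
        stats = skeleton_statistics(cylinder_skeleton)
        assert stats["n_endpoints"] == 2
        assert stats["n_junctions"] == 0
        assert stats["n_branches"] == 1
        assert stats["total_length_um"] == pytest.approx(40.0, rel=0.10)

    def test_skeleton_subset_of_mask(self, cylinder_mask, cylinder_skeleton):
        assert not np.any(cylinder_skeleton.voxels & ~cylinder_mask.voxels)

    def test_trees_equal_object_count(self):
        vox = np.zeros((7, 40, 40), np.uint8)
        vox[2:5, 5:30, 5:8] = 1
        vox[2:5, 5:30, 20:23] = 1
        mask = BinaryMask(vox, (0.5, 0.5, 0.5))
        skel = skeletonize_3d(mask)
        assert skel.n_trees == compute_volume_coverage(mask)[2] == 2

    def test_torus_single_cycle(self):
        mask = ph.make_torus_mask()
        skel = skeletonize_3d(mask)
        stats = skeleton_statistics(skel)
        assert stats["n_endpoints"] == 0
        assert stats["n_trees"] == 1
        assert skel.branches[0].is_cycle
        # cycle length close to the major circumference 2*pi*9
        assert stats["total_length_um"] == pytest.approx(2 * math.pi * 9,
                                                         rel=0.10)

    def test_y_tube_topology(self, y_skeleton):
        stats = skeleton_statistics(y_skeleton)
        assert stats["n_junctions"] == 1
        assert stats["n_triple_points"] == 1
        assert stats["n_endpoints"] == 3
        assert stats["n_branches"] == 3

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_3d(BinaryMask(np.zeros((3, 3, 3), np.uint8),
                                         (1, 1, 1)))
        stats = skeleton_statistics(skel)
        assert all(v == 0 for v in stats.values())

    def test_pruning_removes_short_terminal_branch(self, y_mask):
        pruned = skeletonize_3d(y_mask, prune_below_um=30.0)
        stats = skeleton_statistics(pruned)
        # both arms and the trunk are < 30 um terminal branches; pruning
        # repeatedly strips the shortest until a single path remains
        assert stats["n_junctions"] == 0
        assert stats["n_branches"] <= 1


class TestSkeletonStatistics:
    def test_straight_path_step_sum(self):
        vox = np.zeros((3, 15, 3), np.uint8)
        vox[1, 2:13, 1] = 1  # 11 voxels along y
        skel = skeletonize_3d(BinaryMask(vox, (1.0, 0.5, 1.0)))
        stats = skeleton_statistics(skel)
        assert stats["n_trees"] == 1
        assert stats["n_branches"] == 1
        assert stats["n_junctions"] == 0
        assert stats["n_endpoints"] == 2
        assert stats["total_length_um"] == pytest.approx(5.0)
        assert stats["sum_voxels"] == 11

    def test_length_scales_with_voxel_size(self):
        vox = np.zeros((3, 15, 3), np.uint8)
        vox[1, 2:13, 1] = 1
        l1 = skeleton_statistics(
            skeletonize_3d(BinaryMask(vox, (1.0, 0.5, 1.0))))["total_length_um"]
        l2 = skeleton_statistics(
            skeletonize_3d(BinaryMask(vox, (2.0, 1.0, 2.0))))["total_length_um"]
        assert l2 == pytest.approx(2 * l1)


class TestFeatureRecord:
    def test_quantify_stack_bounds_and_scaling(self, cylinder_mask):
        rec = quantify_stack(cylinder_mask, name="cyl")
        assert 0 <= rec.coverage_pct <= 100
        assert 0 <= rec.sv_ratio <= 1
        assert rec.n_objects == rec.n_trees == 1

        doubled = BinaryMask(cylinder_mask.voxels, (1.0, 1.0, 1.0))
        rec2 = quantify_stack(doubled, name="cyl2x")
        assert rec2.volume_um3 == pytest.approx(8 * rec.volume_um3)
        assert rec2.surface_um3 == pytest.approx(8 * rec.surface_um3)
        assert rec2.skeleton_length_um == pytest.approx(
            2 * rec.skeleton_length_um, rel=1e-6)

    def test_empty_mask_row_of_zeros_with_warning(self):
        mask = BinaryMask(np.zeros((3, 5, 5), np.uint8), (1, 1, 1))
        with pytest.warns(UserWarning):
            rec = quantify_stack(mask, name="empty")
        assert rec.volume_um3 == 0
        assert rec.n_endpoints == 0
        assert rec.thickness_um == 0

    def test_non_binary_input_rejected(self, rng):
        img = VolumetricImage(rng.integers(0, 200, (3, 5, 5)).astype(np.uint8),
                              (1, 1, 1))
        with pytest.raises(ValueError, match="segment"):
            quantify_stack(img)

    def test_mask_image_0_255_accepted(self):
        vox = np.zeros((3, 6, 6), np.uint8)
        vox[1, 2:4, 2:4] = 255
        img = VolumetricImage(vox, (1, 1, 1))
        rec = quantify_stack(img, name="m255")
        assert rec.volume_um3 == 4.0


class TestTextureAndCsv:
    def test_apicobasal_texture_profiles(self, default_phantom):
        spec, image, truth = default_phantom
        skel = skeletonize_3d(truth.mask)
        p_orig, p_mask, p_skel = qt.apicobasal_texture(image, truth.mask, skel)
        np.testing.assert_allclose(p_mask.values,
                                   truth.mask.voxels.mean(axis=(0, 2)))
        # branch zone rows (0.35-0.55 of stalk span) show elevated skeleton mass
        ny = spec.shape[1]
        zone = slice(int(0.38 * ny), int(0.52 * ny))
        outside = np.r_[p_skel.values[: ny // 5]]
        assert p_skel.values[zone].mean() > outside.mean()

    def test_texture_shape_mismatch(self, default_phantom, rng):
        spec, image, truth = default_phantom
        skel = skeletonize_3d(truth.mask)
        other = VolumetricImage(rng.random((2, 3, 3)), (1, 1, 1),
                                bit_depth="float")
        with pytest.raises(ValueError, match="shape"):
            qt.apicobasal_texture(other, truth.mask, skel)

    def test_csv_headers_bit_exact(self, tmp_path, cylinder_mask):
        rec = quantify_stack(cylinder_mask, name="c1")
        files = write_quantification_csvs([rec, rec, rec], tmp_path)
        header = files["quantification"].read_text().splitlines()[0]
        for col in ["Volume [um3]", "PercCov [%]", "SurfaceVol [um3]",
                    "Thickness [um]"]:
            assert col in header
        skel_header = files["skeleton_stats"].read_text().splitlines()[0]
        for col in ["max branch length", "mean branch length", "# of trees",
                    "# of branches", "# of junctions", "# of endpoints",
                    "# of triple points", "# of quadruple points",
                    "sum of voxels"]:
            assert col in skel_header
        import pandas as pd

        assert len(pd.read_csv(files["quantification"])) == 3
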