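import numpy as np
import pytest

from gliaquant import segment as sg
from gliaquant.segment import (
    BinaryMask,
    SegmentationParams,
    compare_methods,
    global_threshold,
    hysteresis_threshold,
    preprocess_stack,
    remove_speckles,
    segment_pipeline,
    simple_3d,
)
from gliaquant.volume_io import VolumetricImage


def _img(data, voxel=(1.0, 1.0, 1.0)):
    return VolumetricImage(np.asarray(data), voxel)


def _rand_hist(rng):
    """Random sparse-ish 8-bit histogram with at least two populated bins."""
    hist = np.zeros(256)
    n_bins = rng.integers(2, 40)
    bins = rng.choice(256, size=n_bins, replace=False)
    hist[bins] = rng.integers(1, 1000, size=n_bins)
    return hist


# ---------------------------------------------------------------------------
# Independent criterion oracles (exhaustive over all 256 candidate thresholds)
# ---------------------------------------------------------------------------

def otsu_between_class_variance(hist, t):
    p = hist / hist.sum()
    w0, w1 = p[: t + 1].sum(), p[t + 1:].sum()
    if w0 == 0 or w1 == 0:
        return -np.inf
    levels = np.arange(256)
    mu0 = (p[: t + 1] * levels[: t + 1]).sum() / w0
    mu1 = (p[t + 1:] * levels[t + 1:]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def max_entropy_criterion(hist, t):
    p = hist / hist.sum()
    w0, w1 = p[: t + 1].sum(), p[t + 1:].sum()
    if w0 <= 0 or w1 <= 0:
        return -np.inf
    h = 0.0
    for chunk, w in ((p[: t + 1], w0), (p[t + 1:], w1)):
        q = chunk[chunk > 0] / w
        h += -(q * np.log(q)).sum()
    return h


def moments_p0(hist):
    p = hist / hist.sum()
    lv = np.arange(256.0)
    m1, m2, m3 = (p * lv).sum(), (p * lv**2).sum(), (p * lv**3).sum()
    # roots of z^2 + c1 z + c0 preserving the first three moments
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    z0, z1 = sorted(np.roots([1.0, c1, c0]).real)
    return (z1 - m1) / (z1 - z0)


class TestGlobalThresholdOracles:
    def test_otsu_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            hist = _rand_hist(rng)
            t = sg.threshold_otsu(hist)
            crits = [otsu_between_class_variance(hist, tt) for tt in range(256)]
            assert otsu_between_class_variance(hist, t) == pytest.approx(
                max(crits), rel=1e-12)

    def test_max_entropy_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            hist = _rand_hist(rng)
            t = sg.threshold_max_entropy(hist)
            crits = [max_entropy_criterion(hist, tt) for tt in range(256)]
            assert max_entropy_criterion(hist, t) == pytest.approx(
                max(crits), rel=1e-12)

    def test_percentile_matches_cumulative_oracle(self, rng):
        for _ in range(10):
            hist = _rand_hist(rng)
            target = rng.uniform(0.2, 0.8)
            t = sg.threshold_percentile(hist, target)
            cum = np.cumsum(hist) / hist.sum()
            assert abs(cum[t] - target) == pytest.approx(
                min(abs(cum[tt] - target) for tt in range(256)), abs=1e-15)

    def test_moments_matches_p0_oracle(self, rng):
        for _ in range(10):
            hist = _rand_hist(rng)
            t = sg.threshold_moments(hist)
            p0 = moments_p0(hist)
            cum = np.cumsum(hist) / hist.sum()
            assert abs(cum[t] - p0) == pytest.approx(
                min(abs(cum[tt] - p0) for tt in range(256)), abs=1e-12)

    def test_two_value_image_otsu(self):
        data = np.concatenate([np.full(5000, 20), np.full(5000, 200)])
        img = _img(data.reshape(10, 10, 100).astype(np.uint8))
        t, mask = global_threshold(img, "otsu")
        assert 20 <= t < 200
        assert mask.voxels.sum() == 5000

    def test_two_value_image_percentile_half(self):
        data = np.concatenate([np.full(5000, 20), np.full(5000, 200)])
        img = _img(data.reshape(10, 10, 100).astype(np.uint8))
        _, mask = global_threshold(img, "percentile", percentile_target=0.5)
        frac = mask.foreground_fraction()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="constant"):
            global_threshold(_img(np.full((4, 4, 4), 9, np.uint8)), "otsu")

    def test_foreground_monotone_in_threshold(self, rng):
        data = rng.integers(0, 256, (6, 20, 20)).astype(np.uint8)
        img = _img(data)
        fracs = [(data > t).mean() for t in range(0, 250, 25)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        del img


class TestHysteresis:
    def test_low_equals_high_matches_global(self, rng):
        data = rng.integers(0, 256, (6, 16, 16)).astype(np.uint8)
        img = _img(data)
        t, gmask = global_threshold(img, "otsu")
        hmask = hysteresis_threshold(img, high=t, low=t)
        np.testing.assert_array_equal(hmask.voxels, gmask.voxels)

    def test_halo_kept_detached_blob_dropped(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[4:6, 2:4, 2:4] = 220       # bright core
        data[4:6, 4:6, 2:4] = 100       # touching mid halo
        data[4:6, 7:9, 7:9] = 100       # detached mid blob
        mask = hysteresis_threshold(_img(data), high=200, low=80)
        # flood-fill oracle: core + connected halo
        assert mask.voxels[4, 2, 2] == 1
        assert mask.voxels[4, 4, 2] == 1
        assert mask.voxels[4, 7, 7] == 0
        assert mask.voxels.sum() == 16

    def test_no_seed_empty_mask(self):
        data = np.full((4, 4, 4), 50, np.uint8)
        data[0, 0, 0] = 60
        mask = hysteresis_threshold(_img(data), high=200, low=40)
        assert mask.voxels.sum() == 0

    def test_low_above_high_rejected(self, rng):
        data = rng.integers(0, 256, (4, 8, 8)).astype(np.uint8)
        with pytest.raises(ValueError, match="exceeds"):
            hysteresis_threshold(_img(data), high=100, low=150)


class TestSimple3dAndSpeckles:
    def test_small_component_discarded(self):
        data = np.zeros((8, 20, 20), np.uint8)
        data[2:6, 2:7, 2:7] = 255   # 100 voxels
        data[1, 15, 15] = 255
        data[1, 15, 16] = 255
        data[1, 16, 15] = 255       # 3-voxel blob
        labels = simple_3d(_img(data), 128, min_object_vox=10)
        assert labels.max() == 1
        assert (labels > 0).sum() == 100

    def test_min_one_equals_plain_threshold(self, rng):
        data = rng.integers(0, 256, (4, 10, 10)).astype(np.uint8)
        labels = simple_3d(_img(data), 128, min_object_vox=1)
        np.testing.assert_array_equal(labels > 0, data > 128)

    def test_empty_image(self):
        labels = simple_3d(_img(np.zeros((3, 3, 3), np.uint8)), 10)
        assert labels.max() == 0

    def test_remove_speckles_component_oracle(self):
        data = np.zeros((10, 30, 30), np.uint8)
        data[1:6, 1:11, 1:11] = 1     # 500 voxels
        data[8, 20:23, 20:23] = 1     # 9 voxels
        data[0, 28, 28:30] = 1        # 2 voxels
        mask = BinaryMask(data, (1, 1, 1))
        out = remove_speckles(mask, 10)
        assert out.voxels.sum() == 500

    def test_remove_speckles_zero_is_identity(self, rng):
        data = (rng.random((5, 8, 8)) > 0.5).astype(np.uint8)
        mask = BinaryMask(data, (1, 1, 1))
        np.testing.assert_array_equal(remove_speckles(mask, 0).voxels, data)

    def test_remove_speckles_never_adds_and_idempotent(self, rng):
        data = (rng.random((6, 12, 12)) > 0.7).astype(np.uint8)
        mask = BinaryMask(data, (1, 1, 1))
        once = remove_speckles(mask, 5)
        assert not np.any(once.voxels & ~data)
        twice = remove_speckles(once, 5)
        np.testing.assert_array_equal(once.voxels, twice.voxels)

    def test_all_below_min_empty(self):
        data = np.zeros((4, 4, 4), np.uint8)
        data[1, 1, 1] = 1
        assert remove_speckles(BinaryMask(data, (1, 1, 1)), 10).voxels.sum() == 0


class TestPreprocess:
    def test_disabled_is_identity(self, rng):
        data = rng.integers(0, 256, (4, 10, 10)).astype(np.uint8)
        params = SegmentationParams(median_radius_vox=(0, 0, 0),
                                    rolling_ball_radius_px=0)
        out = preprocess_stack(_img(data), params)
        np.testing.assert_array_equal(out.voxels, data)

    def test_median_removes_speckle_oracle(self):
        data = np.full((5, 9, 9), 50, np.uint8)
        data[2, 4, 4] = 255
        params = SegmentationParams(median_radius_vox=(1, 1, 1),
                                    rolling_ball_radius_px=0)
        out = preprocess_stack(_img(data), params)
        # brute-force 3x3x3 median at the speckle
        block = data[1:4, 3:6, 3:6].ravel()
        assert out.voxels[2, 4, 4] == np.median(block)
        assert out.voxels[2, 4, 4] == 50

    def test_rolling_ball_flattens_background(self):
        yy = np.linspace(0, 40, 64)
        background = np.tile(yy[:, None], (1, 64))
        data = np.tile(background[None], (2, 1, 1))
        data[:, 30:34, 30:34] += 150.0  # small object atop gradient
        params = SegmentationParams(median_radius_vox=(0, 0, 0),
                                    rolling_ball_radius_px=20)
        out = preprocess_stack(
            VolumetricImage(data, (1, 1, 1), bit_depth="float"), params)
        assert out.voxels[0, 5, 5] < 5.0          # background suppressed
        assert out.voxels[0, 31, 31] > 100.0      # object retained


class TestPipelines:
    def test_cytosol_on_soma_phantom(self):
        from gliaquant import phantom as ph

        spec = ph.PhantomSpec(shape=(8, 120, 80), noise_gaussian_sd=4.0, seed=3)
        clean, truth = ph.generate_glia_phantom(spec)
        degraded = ph.degrade_stack(clean, spec)
        mask = segment_pipeline(degraded, "cytosol")
        truth_frac = truth.mask.voxels.mean()
        assert mask.foreground_fraction() == pytest.approx(truth_frac, rel=0.2)

    def test_membrane_on_hollow_shell(self):
        z, y, x = np.mgrid[0:20, 0:20, 0:20]
        r = np.sqrt((z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2)
        shell = ((r >= 5) & (r <= 7)).astype(np.float64) * 200 + 5
        mask = segment_pipeline(
            VolumetricImage(shell, (1, 1, 1), bit_depth="float"), "membrane",
            SegmentationParams(median_radius_vox=(0, 1, 1),
                               rolling_ball_radius_px=0, min_object_vox=10))
        assert mask.voxels[10, 10, 10] == 0      # hollow center
        assert mask.voxels.sum() > 100

    def test_all_zero_stack_reports_stage(self):
        img = _img(np.zeros((4, 8, 8), np.uint8))
        with pytest.raises(ValueError, match="stage"):
            segment_pipeline(img, "cytosol",
                             SegmentationParams(median_radius_vox=(0, 0, 0),
                                                rolling_ball_radius_px=0))

    def test_unknown_profile(self, small_stack):
        with pytest.raises(ValueError, match="profile"):
            segment_pipeline(small_stack, "nuclear")


class TestCompareMethods:
    def test_two_value_image_all_global_methods_agree(self):
        data = np.concatenate([np.full(5000, 20), np.full(5000, 200)])
        img = _img(data.reshape(10, 10, 100).astype(np.uint8))
        recs = compare_methods(img, preprocess_variants=(False,))
        masks = {r["method"]: r["mask"] for r in recs}
        ref = masks["otsu"].voxels
        for m in ("moments", "percentile", "max_entropy"):
            np.testing.assert_array_equal(masks[m].voxels, ref)

    def test_constant_image_failure_rows(self):
        img = _img(np.full((4, 8, 8), 9, np.uint8))
        recs = compare_methods(img, preprocess_variants=(False,))
        assert len(recs) == 6
        assert all(r["mask"] is None and r["error"] for r in recs)

    def test_record_shape_contract(self, rng):
        data = rng.integers(0, 256, (4, 12, 12)).astype(np.uint8)
        params = SegmentationParams(median_radius_vox=(0, 1, 1),
                                    rolling_ball_radius_px=0)
        recs = compare_methods(_img(data), params)
        assert len(recs) == 12  # 6 methods x (raw, preprocessed)
        assert {r["method"] for r in recs} == set(sg.ALL_METHODS)
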