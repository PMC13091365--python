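"""Vessel morphometry operations: enhancement, vesselness, thresholding,
binarization, skeleton metrics and projections."""

import numpy as np
import pytest

from tumorvasc import synthkit, vesselquant as vq


class TestClahe3d:
    def test_constant_volume_stays_constant(self):
        out = vq.clahe3d(np.full((32, 32, 16), 0.4))
        assert np.ptp(out) == 0.0

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(1)
        out = vq.clahe3d(rng.uniform(0, 5.0, (32, 32, 16)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_low_contrast_tube_contrast_boosted(self):
        """A 5% contrast tube gains at least 2x tube/background contrast."""
        vol = np.full((48, 48, 48), 0.5)
        vol[22:27, :, 22:27] = 0.55
        out = vq.clahe3d(vol, tile_grid=(2, 2, 2))
        c_in = (0.55 - 0.5) / 0.5
        tube = out[24, 24, 24]
        bg = out[5, 5, 5]
        c_out = (tube - bg) / max(bg, 1e-6)
        assert c_out >= 2.0 * c_in

    def test_fixed_value_range_makes_mapping_series_consistent(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1.0, (24, 24, 24))
        scaled = a * 0.5
        out_a = vq.clahe3d(a, value_range=(0.0, 1.0), tile_grid=(2, 2, 2))
        out_s = vq.clahe3d(scaled, value_range=(0.0, 1.0), tile_grid=(2, 2, 2))
        # the weaker dataset must map strictly lower, not be re-stretched
        assert out_s.mean() < out_a.mean()


class TestFrangi:
    def test_constant_volume_zero_response(self):
        vn = vq.frangi_vesselness(np.ones((32, 32, 32)), voxel_size=20.0)
        assert np.allclose(vn.response, 0.0)

    @pytest.mark.parametrize("diameter", [60.0, 80.0, 100.0, 120.0, 140.0])
    def test_scale_argmax_matches_diameter(self, diameter):
        """Per-scale response peaks at the true tube diameter +/- one step."""
        ph = synthkit.tube_phantom(
            (1.28, 1.28, 1.28), (0.0, 0.63, 0.63), (1.28, 0.63, 0.63), diameter
        )
        vn = vq.frangi_vesselness(ph.absorption_map, voxel_size=20.0)
        center = (slice(8, 56), 31, 31)
        per_scale = [
            vn.scale_responses[k][center].mean()
            for k in range(len(vn.scales_used))
        ]
        best = vn.scales_used[int(np.argmax(per_scale))]
        assert abs(best - diameter) <= 20.0

    def test_tube_beats_sphere(self):
        """Equal-contrast tube out-scores a solid sphere of equal diameter."""
        tube = synthkit.tube_phantom(
            (1.28, 1.28, 1.28), (0.0, 0.63, 0.63), (1.28, 0.63, 0.63), 100.0
        ).absorption_map
        sphere = np.zeros_like(tube)
        zz, yy, xx = np.mgrid[0:64, 0:64, 0:64]
        sphere[(zz - 31) ** 2 + (yy - 31) ** 2 + (xx - 31) ** 2 <= 2.5**2] = 1.0
        gamma = 0.2  # shared so the two responses are comparable
        vt = vq.frangi_vesselness(tube, voxel_size=20.0, gamma=gamma)
        vs = vq.frangi_vesselness(sphere, voxel_size=20.0, gamma=gamma)
        assert vt.response.max() > vs.response.max()

    def test_anisotropic_voxels_resampled(self):
        vol = np.zeros((32, 32, 64))
        vol[14:18, :, 30:38] = 1.0  # 80 um wide at (20, 20, 10) um voxels
        vn = vq.frangi_vesselness(vol, voxel_size=(20.0, 20.0, 10.0))
        assert vn.voxel_size == 20.0
        assert vn.response.shape == (32, 32, 32)


class TestThresholds:
    def test_two_value_histogram_split(self):
        rng = np.random.default_rng(3)
        vol = np.where(rng.uniform(size=(20, 20, 20)) < 0.5, 0.2, 0.8)
        thr = vq.auto_threshold(vol)
        assert 0.2 < thr < 0.8

    def test_otsu_equals_brute_force_between_class_variance(self):
        """256-bin exhaustive between-class-variance maximizer oracle."""
        rng = np.random.default_rng(4)
        vol = np.concatenate(
            [rng.normal(0.3, 0.05, 4000), rng.normal(0.7, 0.05, 2000)]
        ).clip(0, 1)
        thr = vq.auto_threshold(vol)
        hist, edges = np.histogram(vol, bins=256, range=(vol.min(), vol.max()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        best, best_var = None, -1.0
        for k in range(1, 256):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best = var, centers[k - 1 : k + 1].mean()
        assert thr == pytest.approx(best, abs=(vol.max() - vol.min()) / 128)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            vq.auto_threshold(np.full((10, 10, 10), 0.5))

    def test_policy_reuses_without_recompute(self, caplog):
        import logging

        policy = vq.ThresholdPolicy(0.3, source_id="ref")
        with caplog.at_level(logging.INFO, logger="tumorvasc.vesselquant"):
            v1 = policy.get("ds1")
            v2 = policy.get("ds2")
        assert v1 == v2 == 0.3
        assert policy.n_reused == 2
        assert sum("reused" in rec.message for rec in caplog.records) == 2


class TestBinarizeAndVOI:
    def test_threshold_above_max_gives_empty(self):
        vn = np.random.default_rng(5).uniform(0, 0.9, (16, 16, 16))
        assert not vq.binarize_and_clean(vn, 1.0).any()

    def test_small_components_removed_large_kept(self):
        vol = np.zeros((32, 32, 32))
        vol[4:6, 4:6, 4:6] = 1.0  # 8 voxels -> removed at min 27
        vol[16:21, 10:26, 16:21] = 1.0  # 400 voxels -> kept
        mask = vq.binarize_and_clean(vol, 0.5, min_component=27)
        assert not mask[4:6, 4:6, 4:6].any()
        assert mask[16:21, 10:26, 16:21].all()

    def test_vvf_half_filled_voi(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[:, :, :10] = True  # half of a 20-voxel-deep VOI
        voi = vq.VOISpec(origin=(0.0, 0.0, 0.0), size=(0.8, 0.8, 0.4))
        assert vq.volumetric_vessel_fraction(mask, voi, 20.0) == pytest.approx(50.0)

    def test_voi_outside_bounds_rejected(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        voi = vq.VOISpec(origin=(0.0, 0.0, 0.0), size=(4.0, 4.0, 2.0))
        with pytest.raises(ValueError):
            vq.volumetric_vessel_fraction(mask, voi, 20.0)

    def test_empty_mask_zero_fraction(self):
        mask = np.zeros((40, 40, 40), dtype=bool)
        voi = vq.VOISpec(origin=(0.0, 0.0, 0.0), size=(0.4, 0.4, 0.4))
        assert vq.volumetric_vessel_fraction(mask, voi, 20.0) == 0.0


class TestSkeleton:
    def test_empty_mask(self):
        assert vq.skeletonize_mask(np.zeros((10, 10, 10), bool)) == (0.0, 0, 0)

    def test_straight_tube_length(self):
        """A 2 mm straight tube skeletonizes to ~2 mm of centerline."""
        ph = synthkit.tube_phantom(
            (2.0, 0.4, 0.4), (0.0, 0.2, 0.2), (2.0, 0.2, 0.2), 120.0
        )
        length, branches, segments = vq.skeletonize_mask(ph.mask, 20.0)
        assert length == pytest.approx(2.0, rel=0.05)
        assert branches == 0
        assert segments == 1

    def test_y_junction_counts(self):
        mask = np.zeros((40, 40, 5), dtype=bool)
        mask[5:21, 20, 2] = True       # stem
        mask[20:35, 20:35, 2][np.eye(15, dtype=bool)] = True   # arm 1
        arm2 = np.eye(15, dtype=bool)[:, ::-1]
        mask[20:35, 6:21, 2][arm2] = True                       # arm 2
        length, branches, segments = vq.skeletonize_mask(mask, 20.0)
        assert branches == 1
        assert segments == 3


class TestProjections:
    def test_mip_constant_and_single_voxel(self):
        vol = np.full((8, 8, 8), 0.3)
        assert np.allclose(vq.max_intensity_projection(vol), 0.3)
        vol2 = np.zeros((8, 8, 8))
        vol2[3, 5, 2] = 1.0
        mip = vq.max_intensity_projection(vol2)
        assert mip[3, 5] == 1.0 and mip.sum() == 1.0

    def test_mip_monotone(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1, (8, 8, 8))
        b = a + rng.uniform(0, 1, (8, 8, 8))
        assert np.all(
            vq.max_intensity_projection(a) <= vq.max_intensity_projection(b)
        )

    def test_projected_area_solid_bar(self):
        mip = np.zeros((100, 100))
        mip[10:60, 20:25] = 1.0  # 50 x 5 px at 20 um -> 1.0 x 0.1 mm
        total, mean_c, n = vq.projected_vessel_area(mip, 0.5, pixel_size=20.0)
        assert total == pytest.approx(0.1, rel=1e-6)
        assert n == 1

    def test_mean_component_of_two_bars(self):
        mip = np.zeros((200, 200))
        mip[10:60, 20:25] = 1.0    # 0.1 mm^2
        mip[100:175, 100:110] = 1.0  # 0.3 mm^2
        total, mean_c, n = vq.projected_vessel_area(mip, 0.5, pixel_size=20.0)
        assert n == 2
        assert mean_c == pytest.approx(0.2, rel=1e-6)

    def test_speckle_below_min_particle_removed(self):
        rng = np.random.default_rng(7)
        mip = (rng.uniform(size=(64, 64)) > 0.95).astype(float)
        total, mean_c, n = vq.projected_vessel_area(
            mip, 0.5, min_particle=0.01, pixel_size=20.0
        )
        assert (total, mean_c, n) == (0.0, 0.0, 0)
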