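"""Parcellation: centroids, masks, splitting, morphology, DP/CTR."""

import numpy as np
import pytest

from tonomap.segmentation import (
    AreaMask,
    FrequencyDomain,
    SegmentationParams,
    boundary_intersection_points,
    close_disk,
    compute_domain_centroid,
    detect_tone_low_responsive,
    disk_roi,
    dividing_distance,
    extract_domain_mask,
    identify_ctr,
    identify_dp,
    merge_domains_to_area,
    open_disk,
    resolve_area_overlaps,
    split_overlapping_domains,
)

from conftest import gaussian_bump


class TestDomainCentroid:
    def test_symmetric_bump_centroid_at_center(self):
        mag = gaussian_bump((64, 64), (30, 40), 6.0)
        roi = disk_roi((64, 64), (30, 40), 15)
        centroid, peak = compute_domain_centroid(mag, roi)
        assert np.allclose(centroid, (30, 40), atol=0.1)
        assert np.isclose(peak, 1.0)

    def test_two_pixel_hand_computation(self):
        mag = np.zeros((4, 4))
        p1, p2 = (1, 1), (3, 2)  # (x, y)
        mag[p1[1], p1[0]] = 3.0
        mag[p2[1], p2[0]] = 1.0
        roi = np.zeros((4, 4), dtype=bool)
        roi[p1[1], p1[0]] = roi[p2[1], p2[0]] = True
        centroid, peak = compute_domain_centroid(mag, roi)
        com = (3 * np.array(p1) + 1 * np.array(p2)) / 4.0
        assert np.allclose(centroid, (np.array(p1) + com) / 2.0)
        assert peak == 3.0

    def test_roi_translation_robustness(self):
        mag = gaussian_bump((64, 64), (30, 40), 5.0)
        c1, _ = compute_domain_centroid(mag, disk_roi((64, 64), (30, 40), 16))
        c2, _ = compute_domain_centroid(mag, disk_roi((64, 64), (33, 38), 16))
        assert np.linalg.norm(c1 - c2) < 0.5

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty seed"):
            compute_domain_centroid(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_zero_response_roi_rejected(self):
        with pytest.raises(ValueError, match="empty seed"):
            compute_domain_centroid(np.zeros((4, 4)), np.ones((4, 4), bool))


class TestExtractDomainMask:
    def test_level_set_radius_of_gaussian(self):
        sigma = 20.0
        mag = gaussian_bump((128, 128), (64, 64), sigma)
        mask = extract_domain_mask(mag, (64, 64), 1.0, 0.60)
        r_expected = sigma * np.sqrt(2 * np.log(1 / 0.6))
        r_measured = np.sqrt(mask.sum() / np.pi)
        assert abs(r_measured - r_expected) < 1.0

    def test_threshold_to_one_keeps_only_peak_region(self):
        mag = gaussian_bump((64, 64), (32, 32), 8.0)
        mask = extract_domain_mask(mag, (32, 32), 1.0, 0.999)
        assert mask[32, 32]
        assert mask.sum() < 20

    def test_connectivity_excludes_distant_component(self):
        mag = gaussian_bump((64, 128), (30, 30), 5.0) + gaussian_bump(
            (64, 128), (100, 30), 5.0
        )
        mask = extract_domain_mask(mag, (30, 30), 1.0, 0.6)
        assert mask[30, 30] and not mask[30, 100]

    def test_centroid_below_threshold_rejected(self):
        mag = gaussian_bump((64, 64), (32, 32), 5.0)
        with pytest.raises(ValueError, match="threshold"):
            extract_domain_mask(mag, (5, 5), 1.0, 0.6)

    def test_lower_threshold_mask_contains_higher(self):
        rng = np.random.default_rng(0)
        mag = gaussian_bump((96, 96), (48, 48), 10.0) + np.abs(
            rng.normal(0, 0.01, (96, 96))
        )
        m60 = extract_domain_mask(mag, (48, 48), mag.max(), 0.60)
        m40 = extract_domain_mask(mag, (48, 48), mag.max(), 0.40)
        assert np.all(m40 | ~m60)  # m60 subset of m40


class TestSplitOverlappingDomains:
    def _domain(self, area, center, amp, mask):
        return FrequencyDomain(area, 10.0, np.asarray(center, float), amp, mask)

    def test_amplitude_proportional_distance(self):
        assert dividing_distance(2.0, 1.0, 300.0) == 200.0
        assert dividing_distance(1.0, 2.0, 300.0) == 100.0

    def test_equal_amplitudes_split_at_midpoint_symmetric(self):
        shape = (64, 96)
        a = self._domain("A1", (30, 32), 1.0, disk_roi(shape, (30, 32), 15))
        b = self._domain("A2", (50, 32), 1.0, disk_roi(shape, (50, 32), 15))
        na, nb = split_overlapping_domains(a, b)
        assert not np.any(na.mask & nb.mask)
        # mirror symmetry about the x = 40 midline
        assert abs(int(na.mask.sum()) - int(nb.mask.sum())) <= na.mask.shape[0]
        assert na.mask[:, :41].sum() == na.mask.sum()  # A keeps its side
        assert nb.mask[:, 41:].sum() == nb.mask.sum()

    def test_non_overlapping_unchanged(self):
        shape = (64, 128)
        a = self._domain("A1", (20, 32), 1.0, disk_roi(shape, (20, 32), 10))
        b = self._domain("A2", (100, 32), 1.0, disk_roi(shape, (100, 32), 10))
        na, nb = split_overlapping_domains(a, b)
        assert np.array_equal(na.mask, a.mask)
        assert np.array_equal(nb.mask, b.mask)

    def test_coincident_centroids_rejected(self):
        shape = (32, 32)
        m = disk_roi(shape, (16, 16), 8)
        a = self._domain("A1", (16, 16), 1.0, m)
        b = self._domain("A2", (16, 16), 1.0, m.copy())
        with pytest.raises(ValueError, match="degenerate"):
            split_overlapping_domains(a, b)


class TestDiskMorphology:
    def test_opening_removes_thin_bridge(self):
        # two r=50 disks joined by an 11-px-wide bridge; a 30-px opening
        # removes the bridge but keeps the disks
        mask = np.zeros((200, 400), dtype=bool)
        mask |= disk_roi(mask.shape, (100, 100), 50)
        mask |= disk_roi(mask.shape, (300, 100), 50)
        mask[95:106, 100:300] = True
        opened = open_disk(mask, 30)
        assert not opened[100, 200]  # bridge midpoint gone
        assert opened[100, 100] and opened[100, 300]
        from skimage.measure import label

        assert label(opened).max() == 2

    def test_closing_fuses_across_250px_gap(self):
        # two elongated blobs with facing edges 250 px apart fuse under a
        # 150-px closing (a gap narrower than the disk diameter)
        mask = np.zeros((700, 700), dtype=bool)
        mask[50:650, 100:200] = True
        mask[50:650, 450:550] = True  # gap columns 200..449 (250 px)
        closed = close_disk(mask, 150)
        from skimage.measure import label

        assert label(closed).max() == 1
        assert closed[350, 325]  # gap midpoint filled

    def test_large_convex_mask_stable_under_open_close(self):
        mask = disk_roi((500, 500), (250, 250), 200)
        out = close_disk(open_disk(mask, 30), 150)
        assert (out ^ mask).sum() / mask.sum() < 0.02

    def test_agrees_with_skimage_on_small_disks(self):
        # independent oracle for the EDT-based implementation
        from skimage.morphology import disk, opening

        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(80, 80)) < 0.4
        ours = open_disk(mask, 3)
        theirs = opening(mask, disk(3))
        assert (ours ^ theirs).mean() < 0.02


class TestMergeAndResolve:
    def test_empty_input_gives_absent_area(self):
        assert merge_domains_to_area([], SegmentationParams()) is None

    def test_merge_unions_and_smooths(self):
        shape = (200, 200)
        params = SegmentationParams(open_radius_px=5, close_radius_px=20)
        doms = [
            FrequencyDomain("A1", f, np.array(c, float), 1.0,
                            disk_roi(shape, c, 25))
            for f, c in ((3.0, (60, 100)), (10.0, (100, 100)), (30.0, (140, 100)))
        ]
        am = merge_domains_to_area(doms, params)
        assert am.area == "A1"
        assert am.frequencies == (3.0, 10.0, 30.0)
        from skimage.measure import label

        assert label(am.mask).max() == 1

    def test_two_circle_chord_through_boundary_intersections(self):
        # analytic circle-geometry oracle
        r, d = 60.0, 80.0
        shape = (240, 300)
        c1, c2 = (100, 120), (100 + d, 120)
        m1 = disk_roi(shape, c1, r)
        m2 = disk_roi(shape, c2, r)
        pts = boundary_intersection_points(m1, m2)
        assert len(pts) == 2
        x = d / 2
        y = np.sqrt(r**2 - x**2)
        expected = {(c1[0] + x, 120 - y), (c1[0] + x, 120 + y)}
        for p in pts:
            assert min(np.hypot(p[0] - ex, p[1] - ey) for ex, ey in expected) < 2.0

    def test_resolve_splits_circle_overlap(self):
        r, d = 60.0, 80.0
        shape = (240, 300)
        a = AreaMask("A1", disk_roi(shape, (100, 120), r), peak_amplitude=1.0)
        b = AreaMask("A2", disk_roi(shape, (180, 120), r), peak_amplitude=1.0)
        out = resolve_area_overlaps([a, b])
        ma, mb = out[0].mask, out[1].mask
        assert not np.any(ma & mb)
        # each keeps its own side: the chord is the vertical line x = 140
        assert ma[120, 100] and not ma[120, 180]
        assert mb[120, 180] and not mb[120, 100]
        ys, xs = np.nonzero(ma)
        assert xs.max() <= 141
        ys, xs = np.nonzero(mb)
        assert xs.min() >= 139

    def test_disjoint_masks_unchanged(self):
        shape = (100, 200)
        a = AreaMask("A1", disk_roi(shape, (50, 50), 20), peak_amplitude=1.0)
        b = AreaMask("A2", disk_roi(shape, (150, 50), 20), peak_amplitude=1.0)
        out = resolve_area_overlaps([a, b])
        assert np.array_equal(out[0].mask, a.mask)
        assert np.array_equal(out[1].mask, b.mask)

    def test_a1_vaf_overlap_retained(self):
        shape = (100, 200)
        a = AreaMask("A1", disk_roi(shape, (90, 50), 30), peak_amplitude=1.0)
        b = AreaMask("VAF", disk_roi(shape, (120, 50), 30), peak_amplitude=1.0)
        out = resolve_area_overlaps([a, b])
        assert np.any(out[0].mask & out[1].mask)
        assert np.array_equal(out[0].mask, a.mask)

    def test_nested_masks_rejected(self):
        shape = (100, 100)
        a = AreaMask("A1", disk_roi(shape, (50, 50), 30), peak_amplitude=1.0)
        b = AreaMask("A2", disk_roi(shape, (50, 50), 10), peak_amplitude=1.0)
        with pytest.raises(ValueError, match="containment"):
            resolve_area_overlaps([a, b])

    def test_multi_crossing_falls_back_to_amplitude_split(self):
        # cross-shaped overlap: four boundary intersections
        shape = (120, 120)
        a = np.zeros(shape, bool)
        a[50:70, 10:110] = True
        b = np.zeros(shape, bool)
        b[10:110, 40:60] = True
        out = resolve_area_overlaps([
            AreaMask("A1", a, peak_amplitude=2.0),
            AreaMask("A2", b, peak_amplitude=1.0),
        ])
        assert not np.any(out[0].mask & out[1].mask)


class TestLowResponsiveAreas:
    def _bump_setup(self):
        sigma = 20.0
        mag = gaussian_bump((160, 160), (80, 80), sigma)
        params = SegmentationParams(open_radius_px=3, close_radius_px=8)
        dom = FrequencyDomain("A1", 3.0, np.array([80.0, 80.0]), 1.0,
                              extract_domain_mask(mag, (80, 80), 1.0, 0.6))
        area = AreaMask("A1", dom.mask.copy(), (3.0,), 1.0)
        return mag, params, dom, area, sigma

    def test_fully_covered_union_gives_empty_marginal(self):
        mag, params, dom, _, _ = self._bump_setup()
        big = AreaMask("A1", mag > 0.05, (3.0,), 1.0)
        low = detect_tone_low_responsive({3.0: mag}, [dom], [big], params)
        assert not low.any()

    def test_annulus_between_20_and_60_percent_levels(self):
        mag, params, dom, area, sigma = self._bump_setup()
        low = detect_tone_low_responsive({3.0: mag}, [dom], [area], params)
        r20 = sigma * np.sqrt(2 * np.log(5.0))
        r60 = sigma * np.sqrt(2 * np.log(1 / 0.6))
        expected = np.pi * (r20**2 - r60**2)
        assert abs(low.sum() - expected) < 2 * np.pi * r20  # perimeter tol
        assert not np.any(low & area.mask)

    def test_marginal_mask_shrinks_with_higher_threshold(self):
        mag, params, dom, area, _ = self._bump_setup()
        low20 = detect_tone_low_responsive({3.0: mag}, [dom], [area], params)
        params60 = SegmentationParams(
            low_threshold_frac=0.59, open_radius_px=3, close_radius_px=8
        )
        low60 = detect_tone_low_responsive({3.0: mag}, [dom], [area], params60)
        assert low60.sum() < low20.sum()


class TestDPandCTR:
    def test_strictly_dorsoposterior_region_kept(self, identity_transform):
        # posterior = smaller AP = smaller x; dorsal = smaller DV = smaller y
        a1 = np.zeros((200, 200), bool)
        a1[100:140, 100:140] = True
        low = np.zeros_like(a1)
        low[40:80, 40:80] = True  # strictly up-left of A1
        dp = identify_dp(low, a1, identity_transform)
        assert np.array_equal(dp.mask, low)

    def test_ventral_region_excluded(self, identity_transform):
        a1 = np.zeros((200, 200), bool)
        a1[100:140, 100:140] = True
        low = np.zeros_like(a1)
        low[160:190, 100:140] = True  # ventral of A1
        assert not identify_dp(low, a1, identity_transform).mask.any()

    def test_l_shape_keeps_only_dorsoposterior_quadrant(self, identity_transform):
        a1 = np.zeros((200, 200), bool)
        a1[100:140, 100:140] = True
        low = np.zeros_like(a1)
        low[60:90, 60:180] = True  # dorsal strip
        low[60:180, 60:90] = True  # posterior strip
        dp = identify_dp(low, a1, identity_transform)
        assert dp.mask[70, 70]
        assert not dp.mask[70, 150]  # dorsal but anterior
        assert not dp.mask[150, 70]  # posterior but ventral

    def test_empty_a1_rejected(self, identity_transform):
        with pytest.raises(ValueError):
            identify_dp(np.ones((10, 10), bool), np.zeros((10, 10), bool),
                        identity_transform)

    def _ctr_fixture(self, gap=True):
        shape = (200, 200)
        masks = {
            "A1": AreaMask("A1", np.zeros(shape, bool)),
            "AAF": AreaMask("AAF", np.zeros(shape, bool)),
            "VAF": AreaMask("VAF", np.zeros(shape, bool)),
            "A2": AreaMask("A2", np.zeros(shape, bool)),
        }
        masks["A1"].mask[80:140, 40:80] = True
        x0 = 140 if gap else 81
        masks["AAF"].mask[80:140, x0:180] = True
        masks["VAF"].mask[160:190, 40:80] = True
        masks["A2"].mask[160:190, 140:180] = True
        low = np.zeros(shape, bool)
        if gap:
            low[90:130, 90:130] = True
        return masks, low

    def test_ctr_recovered_inside_gap(self, identity_transform):
        masks, low = self._ctr_fixture(gap=True)
        aaf_centroids = np.array([[160.0, 90.0], [160.0, 130.0]])
        ctr = identify_ctr(low, masks, aaf_centroids, identity_transform)
        assert ctr.mask.any()
        assert np.array_equal(ctr.mask, low)  # entire gap region kept
        for am in masks.values():
            assert not np.any(ctr.mask & am.mask)

    def test_zero_gap_gives_empty_ctr(self, identity_transform):
        masks, low = self._ctr_fixture(gap=False)
        aaf_centroids = np.array([[120.0, 90.0], [120.0, 130.0]])
        ctr = identify_ctr(low, masks, aaf_centroids, identity_transform)
        assert ctr.mask.sum() == 0

    def test_single_aaf_centroid_rejected(self, identity_transform):
        masks, low = self._ctr_fixture()
        with pytest.raises(ValueError, match="unfittable"):
            identify_ctr(low, masks, np.array([[160.0, 90.0]]),
                         identity_transform)


class TestSegmentationParams:
    def test_radii_rescale_with_pixel_size(self):
        p = SegmentationParams.for_pixel_scale(12.89)
        assert np.isclose(p.open_radius_px, 30 * 3.21 / 12.89)
        assert np.isclose(p.close_radius_px, 150 * 3.21 / 12.89)

    @pytest.mark.parametrize("kwargs", [
        dict(threshold_frac=0.0), dict(threshold_frac=1.0),
        dict(low_threshold_frac=-0.1), dict(open_radius_px=0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)
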