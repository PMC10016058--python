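"""Population statistics: overlaps, accuracy, variability, ANOVA, tests."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tonomap import metrics
from tonomap.grid import AnalysisGrid
from tonomap.metrics import (
    MouseRecord,
    PopulationMaps,
    auditory_cortex_centroid,
    centroid_pairwise_distances,
    classification_accuracy,
    geography_metrics,
    group_comparison,
    human_error_metric,
    map_functional_onto_atlas,
    overlap_fraction,
    overlap_fraction_polygon,
    pairwise_population_overlap,
    probability_contours,
    probability_map,
    targeting_accuracy,
    variance_decomposition,
)

GRID = AnalysisGrid(ap_min=-4.0, ap_max=-1.0, dv_min=1.0, dv_max=4.0,
                    step_mm=0.02)


def record(masks_mm=None, centroids=None, mouse_id="m", meta=None):
    """Build a MouseRecord from (AP, DV) boxes: name -> (x0, y0, x1, y1)."""
    rasters, polys = {}, {}
    for name, (x0, y0, x1, y1) in (masks_mm or {}).items():
        poly = box(x0, y0, x1, y1)
        polys[name] = poly
        rasters[name] = GRID.rasterize(poly)
    return MouseRecord(mouse_id=mouse_id, area_rasters=rasters,
                       centroids_mm=centroids or {}, area_polygons=polys,
                       meta=meta or {})


class TestOverlapFraction:
    def test_identical_masks(self):
        m = GRID.rasterize(box(-3, 2, -2, 3))
        assert overlap_fraction(m, m) == 1.0

    def test_disjoint_masks(self):
        a = GRID.rasterize(box(-3.5, 2, -3.0, 2.5))
        b = GRID.rasterize(box(-2.0, 2, -1.5, 2.5))
        assert overlap_fraction(a, b) == 0.0

    def test_half_shifted_unit_squares_both_kernels(self):
        pa, pb = box(-3, 2, -2, 3), box(-2.5, 2, -1.5, 3)
        assert np.isclose(overlap_fraction_polygon(pa, pb), 0.5)
        a, b = GRID.rasterize(pa), GRID.rasterize(pb)
        assert np.isclose(overlap_fraction(a, b), 0.5, atol=0.02)

    def test_denominator_choice(self):
        a = GRID.rasterize(box(-3, 2, -2, 3))
        b = GRID.rasterize(box(-3, 2, -2.5, 3))  # half of a
        assert np.isclose(overlap_fraction(a, b, "a"), 0.5, atol=0.02)
        assert np.isclose(overlap_fraction(a, b, "b"), 1.0)

    def test_empty_denominator_rejected(self):
        m = GRID.rasterize(box(-3, 2, -2, 3))
        with pytest.raises(ValueError, match="empty"):
            overlap_fraction(m, np.zeros_like(m), "b")

    def test_raster_and_polygon_kernels_agree(self, rng):
        for _ in range(5):
            x0, y0 = rng.uniform(-3.5, -2.5), rng.uniform(1.5, 2.5)
            pa = box(x0, y0, x0 + rng.uniform(0.3, 1.0), y0 + rng.uniform(0.3, 1.0))
            pb = box(x0 + 0.2, y0 + 0.1, x0 + 1.0, y0 + 0.8)
            fp = overlap_fraction_polygon(pa, pb)
            fr = overlap_fraction(GRID.rasterize(pa), GRID.rasterize(pb))
            assert abs(fp - fr) < 0.01 + 0.02


class TestFunctionalAtlasMapping:
    ATLAS = {
        "Au1": GRID.rasterize(box(-3.5, 1.8, -1.7, 2.8)),
        "AuD": GRID.rasterize(box(-3.5, 1.3, -1.7, 1.8)),
        "AuV": GRID.rasterize(box(-3.5, 2.8, -1.7, 3.8)),
    }

    def test_rows_sum_to_one(self):
        m = record({"A1": (-3.0, 2.0, -2.0, 3.2), "VAF": (-3.2, 2.9, -2.8, 3.4),
                    "AAF": (-2.4, 2.0, -2.0, 2.6), "A2": (-2.6, 2.9, -2.2, 3.3)})
        df = map_functional_onto_atlas(m, self.ATLAS)
        assert np.allclose(df.sum(axis=1), 1.0, atol=1e-9)

    def test_contained_mask_single_cell(self):
        m = record({"A1": (-3.0, 2.0, -2.5, 2.5)})
        df = map_functional_onto_atlas(m, self.ATLAS, functional_areas=("A1",))
        assert np.isclose(df.loc["A1", "Au1"], 1.0)
        assert df.loc["A1", "outside"] == 0.0

    def test_straddling_mask_splits(self):
        # square symmetric about the Au1/AuV border at DV = 2.8
        m = record({"A1": (-3.0, 2.4, -2.6, 3.2)})
        df = map_functional_onto_atlas(m, self.ATLAS, functional_areas=("A1",))
        assert np.isclose(df.loc["A1", "Au1"], 0.5, atol=0.03)
        assert np.isclose(df.loc["A1", "AuV"], 0.5, atol=0.03)

    def test_absent_area_gives_nan_row(self):
        df = map_functional_onto_atlas(record({}), self.ATLAS,
                                       functional_areas=("A1",))
        assert df.loc["A1"].isna().all()

    def test_classification_accuracy_limits(self):
        inside = record({"A1": (-3.0, 2.0, -2.5, 2.5), "A2": (-2.6, 2.9, -2.2, 3.3)})
        acc = classification_accuracy(inside, self.ATLAS)
        assert acc["A1->Au1"] == 1.0 and acc["A2->AuV"] == 1.0
        outside = record({"A1": (-3.0, 3.9, -2.5, 4.0), "A2": (-3.0, 1.0, -2.5, 1.2)})
        acc = classification_accuracy(outside, self.ATLAS)
        assert acc["A1->Au1"] == 0.0 and acc["A2->AuV"] == 0.0

    def test_constructed_60_percent_overlap(self):
        # A1 box with 60% of its extent inside Au1 (border at DV 2.8)
        m = record({"A1": (-3.0, 2.2, -2.6, 3.2)})  # 1.0 tall, 0.6 above 2.8
        acc = classification_accuracy(m, self.ATLAS)
        assert np.isclose(acc["A1->Au1"], 0.6, atol=0.03)

    def test_targeting_accuracy_set_arithmetic(self):
        au1 = (-3.5, 1.8, -1.7, 2.8)
        m = record({
            "A1": (-3.5, 1.8, -2.6, 2.8),   # left half of Au1
            "VAF": (-2.6, 1.8, -1.7, 2.8),  # right half
            "AAF": (-3.0, 1.0, -2.8, 1.2),  # outside Au1
            "A2": (-3.0, 2.9, -2.6, 3.3),
        })
        acc = targeting_accuracy(m, self.ATLAS)
        assert np.isclose(acc["Au1->A1"], 0.5, atol=0.02)
        assert np.isclose(acc["Au1->primary"], 1.0, atol=0.02)
        assert acc["Au1->primary"] >= acc["Au1->A1"]

    def test_empty_functional_areas_give_zero_targeting(self):
        acc = targeting_accuracy(record({}), self.ATLAS)
        assert acc == {"Au1->A1": 0.0, "Au1->primary": 0.0, "AuV->A2": 0.0}


class TestPairwiseOverlap:
    def test_identical_population(self):
        mice = [record({"A1": (-3, 2, -2, 3)}, mouse_id=f"m{i}") for i in range(4)]
        pop = PopulationMaps(grid=GRID, mice=mice)
        out = pairwise_population_overlap(pop, "A1")
        assert out["mean"] == 1.0
        assert out["n_pairs"] == 12  # 4 * 3 ordered pairs

    def test_41_mice_enumerate_1640_ordered_pairs(self):
        mice = [record({"A1": (-3, 2, -2.8, 2.2)}, mouse_id=f"m{i}")
                for i in range(41)]
        pop = PopulationMaps(grid=GRID, mice=mice)
        assert pairwise_population_overlap(pop, "A1")["n_pairs"] == 1640

    def test_half_overlapping_pair(self):
        mice = [record({"A1": (-3, 2, -2, 3)}), record({"A1": (-2.5, 2, -1.5, 3)})]
        pop = PopulationMaps(grid=GRID, mice=mice)
        assert np.isclose(pairwise_population_overlap(pop, "A1")["mean"],
                          0.5, atol=0.02)

    def test_missing_area_skipped(self):
        mice = [record({"A1": (-3, 2, -2, 3)}, mouse_id=f"m{i}") for i in range(3)]
        mice.append(record({}, mouse_id="m3"))
        pop = PopulationMaps(grid=GRID, mice=mice)
        assert pairwise_population_overlap(pop, "A1")["n_pairs"] == 6


class TestCentroidDistances:
    DOMS = metrics.VARIABILITY_DOMAINS

    def _mice(self, offsets):
        mice = []
        for i, off in enumerate(offsets):
            cents = {d: np.array([-2.8, 2.4]) + off for d in self.DOMS}
            mice.append(MouseRecord(f"m{i}", {}, cents))
        return PopulationMaps(grid=GRID, mice=mice)

    def test_identical_population_zero_distance(self):
        pop = self._mice([np.zeros(2)] * 5)
        out = centroid_pairwise_distances(pop)
        assert out["mean_ap_mm"] == 0.0 and out["mean_dv_mm"] == 0.0

    def test_full_pair_count_41_mice(self):
        pop = self._mice([np.zeros(2)] * 41)
        out = centroid_pairwise_distances(pop)
        assert out["n_pairs"] == out["max_pairs"] == 4 * (41 * 40 // 2)

    def test_missing_domain_reduces_realized_pairs(self):
        pop = self._mice([np.zeros(2)] * 5)
        del pop.mice[0].centroids_mm[self.DOMS[0]]
        out = centroid_pairwise_distances(pop)
        assert out["n_pairs"] == out["max_pairs"] - 4

    def test_gaussian_jitter_closed_form(self, rng):
        sigma = 0.4
        offsets = rng.normal(0, sigma, size=(300, 2))
        out = centroid_pairwise_distances(self._mice(list(offsets)))
        expected = 2 * sigma / np.sqrt(np.pi)
        assert np.isclose(out["mean_ap_mm"], expected, rtol=0.1)
        assert np.isclose(out["mean_dv_mm"], expected, rtol=0.1)


class TestHumanError:
    def test_identical_placements(self):
        marks = np.array([[-2.5, 1.5], [-3.5, 1.5], [-3.5, 2.0]])
        out = human_error_metric(marks, marks)
        assert out == {"ap_mm": 0.0, "dv_mm": 0.0}

    def test_pure_ap_shift(self):
        a = np.array([[-2.5, 1.5], [-3.5, 1.5], [-3.5, 2.0]])
        b = a + [0.09, 0.0]
        out = human_error_metric(a, b)
        assert np.isclose(out["ap_mm"], 0.09)
        assert out["dv_mm"] == 0.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            human_error_metric(np.zeros((2, 2)), np.zeros((3, 2)))


class TestProbabilityContours:
    def _pop(self, rng, n=10, share_center=6):
        mice = []
        for i in range(n):
            if i < share_center:
                b = (-3.0, 2.0, -2.0, 3.0)
            else:
                b = (-3.8 + 0.1 * i, 1.2, -3.3 + 0.1 * i, 1.7)
            mice.append(record({"A1": b}, mouse_id=f"m{i}"))
        return PopulationMaps(grid=GRID, mice=mice)

    def test_fraction_counts_mice(self, rng):
        pop = self._pop(rng)
        frac = probability_map(pop, "A1", filter_radius_um=0)
        iy = np.searchsorted(GRID.dv_centers, 2.5)
        ix = np.searchsorted(GRID.ap_centers, -2.5)
        assert np.isclose(frac[iy, ix], 0.6)

    def test_contours_nested(self, rng):
        pop = self._pop(rng)
        out = probability_contours(pop, "A1")
        frac = out["fraction"]
        prev = None
        for level in out["levels"]:
            region = frac >= level
            if prev is not None:
                assert np.all(prev | ~region)  # region subset of prev
            prev = region
        assert len(out["contours"][0.1]) >= 1

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            probability_map(PopulationMaps(grid=GRID, mice=[]), "A1")


class TestCortexCentroidAndGeography:
    def test_centroid_of_identical_points(self):
        c = {d: np.array([-2.5, 2.1]) for d in metrics.VARIABILITY_DOMAINS}
        assert np.allclose(auditory_cortex_centroid(MouseRecord("m", {}, c)),
                           (-2.5, 2.1))

    def test_centroid_of_square_corners(self):
        pts = [(0, 0), (1, 0), (0, 1), (1, 1)]
        c = dict(zip(metrics.VARIABILITY_DOMAINS, map(np.array, pts)))
        assert np.allclose(auditory_cortex_centroid(MouseRecord("m", {}, c)),
                           (0.5, 0.5))

    def test_missing_domain_named_in_error(self):
        c = {d: np.zeros(2) for d in metrics.VARIABILITY_DOMAINS[:-1]}
        with pytest.raises(ValueError, match="A2"):
            auditory_cortex_centroid(MouseRecord("m", {}, c))

    def _geo_record(self, centroids):
        masks = {"A1": (-3.2, 2.0, -2.8, 2.6), "VAF": (-3.2, 2.8, -2.8, 3.2),
                 "AAF": (-2.4, 2.0, -2.0, 2.6), "A2": (-2.5, 2.8, -2.1, 3.2)}
        r = record(masks, centroids=centroids)
        return r

    def test_collinear_centroids_give_zero_alpha(self):
        c = {("A1", 3.0): np.array([-3.0, 2.0]),
             ("A1", 30.0): np.array([-2.8, 2.0]),
             ("AAF", 3.0): np.array([-2.2, 2.0]),
             ("A2", 3.0): np.array([-2.5, 3.0])}
        g = geography_metrics(self._geo_record(c), GRID)
        assert np.isclose(g.alpha_rad, 0.0, atol=1e-9)

    def test_right_angle_alpha(self):
        c = {("A1", 3.0): np.array([-3.0, 2.0]),
             ("A1", 30.0): np.array([-3.0, 1.5]),
             ("AAF", 3.0): np.array([-2.2, 2.0]),
             ("A2", 3.0): np.array([-2.5, 3.0])}
        g = geography_metrics(self._geo_record(c), GRID)
        assert np.isclose(g.alpha_rad, np.pi / 2)

    def test_touching_masks_zero_border_distance(self):
        masks = {"A1": (-3.2, 2.0, -2.8, 2.6), "VAF": (-3.2, 2.8, -2.8, 3.2),
                 "AAF": (-2.8, 2.0, -2.4, 2.6), "A2": (-2.5, 2.8, -2.1, 3.2)}
        c = {("A1", 3.0): np.array([-3.0, 2.2]),
             ("A1", 30.0): np.array([-2.9, 2.1]),
             ("AAF", 3.0): np.array([-2.6, 2.2]),
             ("A2", 3.0): np.array([-2.3, 3.0])}
        g = geography_metrics(record(masks, centroids=c), GRID)
        assert g.a1_aaf_border_distance_mm < 1e-9
        assert g.ap_extent_mm > 0 and g.dv_extent_mm > 0

    def test_extents_match_union_bounding_box(self):
        c = {("A1", 3.0): np.array([-3.0, 2.0]),
             ("A1", 30.0): np.array([-2.9, 1.9]),
             ("AAF", 3.0): np.array([-2.2, 2.0]),
             ("A2", 3.0): np.array([-2.5, 3.0])}
        g = geography_metrics(self._geo_record(c), GRID)
        assert np.isclose(g.ap_extent_mm, 1.2, atol=0.05)
        assert np.isclose(g.dv_extent_mm, 1.2, atol=0.05)
        assert np.isclose(g.area_mm2["A1"], 0.4 * 0.6, atol=0.02)


class TestVarianceDecomposition:
    def test_null_design_all_unexplained(self, rng):
        df = pd.DataFrame({
            "ap": rng.normal(size=40), "strain": "B6", "sex": "M",
            "age": np.full(40, 8.0),
        })
        shares = variance_decomposition(df, "ap")
        assert shares["strain"] == 0.0 and shares["sex"] == 0.0
        assert np.isclose(shares["unexplained"], 100.0)

    def test_constructed_strain_offset_share(self, rng):
        n = 400
        strain = np.where(rng.uniform(size=n) < 0.5, "CBA", "B6")
        ap = (strain == "CBA") * 0.3 + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"ap": ap, "strain": strain,
                           "sex": rng.choice(["M", "F"], n),
                           "age": rng.uniform(6, 12, n)})
        shares = variance_decomposition(df, "ap")
        p = (strain == "CBA").mean()
        expected = 100 * p * (1 - p) * 0.3**2 / (p * (1 - p) * 0.3**2 + 0.01)
        assert abs(shares["strain"] - expected) < 8.0

    def test_shares_partition_to_100(self, rng):
        df = pd.DataFrame({
            "ap": rng.normal(size=60),
            "strain": rng.choice(["B6", "CBA", "PV"], 60),
            "sex": rng.choice(["M", "F"], 60),
            "age": rng.uniform(6, 12, 60),
        })
        shares = variance_decomposition(df, "ap")
        assert np.isclose(sum(shares.values()), 100.0, atol=0.1)

    def test_aliased_factors_rejected(self, rng):
        strain = rng.choice(["B6", "CBA"], 30)
        df = pd.DataFrame({
            "ap": rng.normal(size=30), "strain": strain,
            "sex": np.where(strain == "B6", "M", "F"),  # perfectly aliased
            "age": np.full(30, 8.0),
        })
        with pytest.raises(ValueError, match="confounded|aliased"):
            variance_decomposition(df, "ap")


class TestGroupComparison:
    def test_identical_samples_capped_at_one(self):
        assert group_comparison([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_enumeration_minimal_p(self):
        # complete separation of 3 vs 3: exact two-sided p = 2/C(6,3) * ...
        assert np.isclose(group_comparison([1, 2, 3], [101, 102, 103]), 0.1)

    def test_bonferroni_multiplication(self):
        raw = group_comparison([1, 2, 3], [101, 102, 103])
        assert np.isclose(group_comparison([1, 2, 3], [101, 102, 103], 3),
                          min(1.0, 3 * raw))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_comparison([1], [2], corrections=0)
        with pytest.raises(ValueError):
            group_comparison([], [1, 2])
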