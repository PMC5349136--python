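import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.draw import disk

from nucleoscan import (
    CalibrationRegions,
    CircleDetection,
    ClusterDecomposition,
    CondensationParams,
    DetectionParams,
    ImagePlane,
    classify,
    cluster_nucleus,
    condensation_ratio,
    default_calibration,
    measure_nucleus,
    nucleolus_rule,
)
from nucleoscan.condensation import NucleusMeasurement, StateRegion, _kmeans_1d
from nucleoscan.errors import EmptySampleError
from nucleoscan.synth import SceneSpec, gen_field
from oracle_utils import exhaustive_kmeans_sse, partition_sse


def make_decomposition(brightest_area_pct: int, diff: float) -> ClusterDecomposition:
    """Two-cluster decomposition with exact area fraction and relative
    brightness difference (binary-exact centroids at the rule boundaries)."""
    c_max = 0.625
    exact_cmin = {0.20: 0.5, 0.30: 0.4375}  # 0.125/0.625, 0.1875/0.625
    c_min = exact_cmin.get(diff, c_max * (1.0 - diff))
    n = 100
    areas = np.array([n - brightest_area_pct, brightest_area_pct])
    assignments = np.repeat([0, 1], areas)
    return ClusterDecomposition(
        assignments=assignments,
        centroids=np.array([c_min, c_max]),
        areas=areas,
        k=2,
    )


class TestKmeans1d:
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12))
    def test_two_cluster_partition_is_globally_optimal(self, values):
        values = np.asarray(values)
        if len(np.unique(values)) < 2:
            return
        labels, centroids, areas = _kmeans_1d(values, 2)
        assert np.isclose(
            partition_sse(values, labels),
            exhaustive_kmeans_sse(values, 2),
            atol=1e-12,
        )

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=10))
    def test_three_cluster_partition_is_globally_optimal(self, values):
        values = np.asarray(values)
        if len(np.unique(values)) < 3:
            return
        labels, _, _ = _kmeans_1d(values, 3)
        assert np.isclose(
            partition_sse(values, labels),
            exhaustive_kmeans_sse(values, 3),
            atol=1e-12,
        )

    def test_matches_sklearn_on_nucleus_sized_sample(self):
        """Independent cross-check: restarted Lloyd's must not beat the DP."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(0.3, 0.05, 120), rng.normal(0.8, 0.04, 60)]
        ).clip(0, 1)
        labels, _, _ = _kmeans_1d(values, 4)
        ours = partition_sse(values, labels)
        km = KMeans(n_clusters=4, n_init=10, random_state=0).fit(
            values.reshape(-1, 1)
        )
        assert ours <= km.inertia_ + 1e-9


class TestClusterNucleus:
    def test_constant_region_degrades_to_single_cluster(self):
        plane = ImagePlane(np.full((64, 64), 0.3))
        dec = cluster_nucleus(plane, CircleDetection(32, 32, 8, 1.0), k=4)
        assert dec.k == 1
        assert dec.areas.sum() == len(dec.assignments)

    def test_bimodal_pixels_split_evenly(self):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 8)
        img[rr, cc] = np.where(np.arange(len(rr)) % 2 == 0, 0.2, 0.9)
        dec = cluster_nucleus(ImagePlane(img), CircleDetection(32, 32, 8, 1.0), k=2)
        assert np.allclose(dec.centroids, [0.2, 0.9])
        assert abs(int(dec.areas[0]) - int(dec.areas[1])) <= 1

    @pytest.mark.parametrize("case", range(10))
    def test_tiny_circles_match_exhaustive_partition(self, case):
        rng = np.random.default_rng(case)
        img = np.zeros((32, 32))
        rr, cc = disk((16, 16), 2)
        img[rr, cc] = rng.uniform(0, 1, len(rr))
        plane = ImagePlane(img)
        dec = cluster_nucleus(plane, CircleDetection(16, 16, 2, 1.0), k=2)
        # assignments are aligned with the disk's pixel order
        values = plane.pixels[rr, cc]
        assert np.isclose(
            partition_sse(values, dec.assignments),
            exhaustive_kmeans_sse(values, 2),
            atol=1e-12,
        )


class TestNucleolusRule:
    """The three-way 15%/20%/30% rule, including its exact boundaries."""

    @pytest.mark.parametrize("area_pct", [10, 15, 16, 50])
    @pytest.mark.parametrize("diff", [0.19, 0.20, 0.25, 0.30, 0.31])
    def test_branch_grid(self, area_pct, diff):
        dec = make_decomposition(area_pct, diff)
        branch = nucleolus_rule(dec)
        if area_pct < 15 and diff >= 0.20:
            expected = "nucleolus_removed"
        elif area_pct > 15 and diff > 0.30:
            expected = "brightest_only"
        else:
            expected = "whole_circle"
        assert branch == expected

    def test_exactly_at_area_threshold_falls_to_whole_circle(self):
        # both area comparisons are strict, so a = 0.15 never triggers either
        assert nucleolus_rule(make_decomposition(15, 0.5)) == "whole_circle"

    def test_single_cluster_decomposition_scores_whole_circle(self):
        dec = ClusterDecomposition(
            assignments=np.zeros(50, dtype=int),
            centroids=np.array([0.4]),
            areas=np.array([50]),
            k=1,
        )
        assert nucleolus_rule(dec) == "whole_circle"

    def test_absolute_difference_switch(self):
        # relative d = (0.625-0.5)/0.625 = 0.2 but absolute d = 0.125
        dec = make_decomposition(10, 0.20)
        assert nucleolus_rule(dec) == "nucleolus_removed"
        params = CondensationParams(relative_difference=False)
        assert nucleolus_rule(dec, params) == "whole_circle"


class TestMeasureNucleus:
    def test_uniform_disk_scores_whole_circle(self):
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 8)
        img[rr, cc] = 0.5
        m = measure_nucleus(ImagePlane(img), CircleDetection(32, 32, 8, 1.0))
        assert m.rule_branch == "whole_circle"
        assert np.isclose(m.intensity, 0.5)
        assert abs(m.effective_radius - 8) <= 1.0

    def test_condensed_morphology_scores_brightest_cluster_only(self):
        # bright core on a dim halo: 40% of the circle area at 0.9 over 0.2
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 10)
        img[rr, cc] = 0.2
        rr, cc = disk((32, 32), np.sqrt(0.4) * 10)
        img[rr, cc] = 0.9
        m = measure_nucleus(ImagePlane(img), CircleDetection(32, 32, 10, 1.0))
        assert m.rule_branch == "brightest_only"
        assert not m.nucleolus_present
        assert np.isclose(m.intensity, 0.9, atol=0.01)
        assert abs(m.effective_radius - np.sqrt(0.4) * 10) <= 1.0

    def test_relaxed_morphology_excludes_the_nucleolus(self):
        # moderate body with a small bright nucleolus: 8% of area at ~2x body
        img = np.zeros((64, 64))
        rr, cc = disk((32, 32), 10)
        img[rr, cc] = 0.45
        rr, cc = disk((34, 34), np.sqrt(0.08) * 10)
        img[rr, cc] = 0.8
        m = measure_nucleus(ImagePlane(img), CircleDetection(32, 32, 10, 1.0))
        assert m.rule_branch == "nucleolus_removed"
        assert m.nucleolus_present
        assert np.isclose(m.intensity, 0.45, atol=0.01)


class TestClassify:
    @pytest.fixture
    def calibration(self):
        return CalibrationRegions(
            regions={
                "apoptotic": StateRegion(0.0, 6.0, 0.7, 1.0),
                "intermediate": StateRegion(7.0, 12.0, 0.5, 0.65),
                "non_apoptotic": StateRegion(7.0, 12.0, 0.0, 0.45),
            }
        )

    def _measurement(self, r, i):
        return NucleusMeasurement(
            circle=CircleDetection(0, 0, 8, 1.0),
            effective_radius=r,
            intensity=i,
            nucleolus_present=False,
            rule_branch="whole_circle",
        )

    def test_containment(self, calibration):
        assert classify(self._measurement(3.0, 0.9), calibration) == "apoptotic"
        assert classify(self._measurement(9.0, 0.3), calibration) == "non_apoptotic"

    def test_intermediate_sits_above_non_apoptotic_at_same_radius(self, calibration):
        # same effective radius, higher intensity -> intermediate
        assert classify(self._measurement(9.0, 0.55), calibration) == "intermediate"

    def test_fallback_to_nearest_region(self, calibration):
        # just outside the apoptotic box
        assert classify(self._measurement(6.2, 0.95), calibration) == "apoptotic"

    def test_equidistant_tie_breaks_by_fixed_label_order(self):
        calibration = CalibrationRegions(
            regions={
                "apoptotic": StateRegion(0.0, 4.0, 0.6, 1.0),
                "intermediate": StateRegion(6.0, 10.0, 0.6, 1.0),
                "non_apoptotic": StateRegion(0.0, 10.0, 0.0, 0.3),
            }
        )
        # point at radius 5, midway between apoptotic and intermediate boxes
        assert classify(self._measurement(5.0, 0.8), calibration) == "apoptotic"

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CalibrationRegions(
                regions={
                    "apoptotic": StateRegion(0, 6, 0.5, 1.0),
                    "intermediate": StateRegion(5, 10, 0.5, 1.0),
                    "non_apoptotic": StateRegion(0, 10, 0.0, 0.4),
                }
            )


class TestCondensationRatio:
    def test_planted_mixture_recovered(self):
        planes = [
            gen_field(SceneSpec(n_nuclei=20, condensed_fraction=0.3, seed=s))[0]
            for s in range(3)
        ]
        res = condensation_ratio(planes, detection=DetectionParams())
        assert res.n_total == 60
        assert abs(res.percent_condensed - 30.0) <= 5.0

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 100.0)])
    def test_pure_fields(self, fraction, expected):
        plane, _ = gen_field(
            SceneSpec(n_nuclei=20, condensed_fraction=fraction, seed=21)
        )
        res = condensation_ratio(plane, detection=DetectionParams())
        assert res.percent_condensed == expected

    def test_every_nucleus_takes_exactly_one_branch(self):
        plane, _ = gen_field(SceneSpec(n_nuclei=20, condensed_fraction=0.5, seed=22))
        res = condensation_ratio(plane, detection=DetectionParams())
        freqs = res.branch_frequencies()
        assert sum(freqs.values()) == res.n_total
        assert res.n_apoptotic + res.n_intermediate + res.n_non_apoptotic == res.n_total

    def test_intensity_scaling_leaves_branches_unchanged(self):
        plane, _ = gen_field(SceneSpec(n_nuclei=15, condensed_fraction=0.4, seed=23))
        res = condensation_ratio(plane, detection=DetectionParams())
        scaled = ImagePlane(plane.pixels * 0.6)
        # same circles, rescaled intensities: branch decisions must not move
        for m in res.measurements:
            m2 = measure_nucleus(scaled, m.circle)
            assert m2.rule_branch == m.rule_branch

    def test_blank_image_raises_empty_sample(self):
        with pytest.raises(EmptySampleError):
            condensation_ratio(ImagePlane(np.zeros((64, 64))))

    def test_small_sample_warns_below_floor(self):
        plane, _ = gen_field(SceneSpec(n_nuclei=5, seed=24))
        with pytest.warns(UserWarning, match="below the recommended"):
            condensation_ratio(plane, detection=DetectionParams())

    def test_default_calibration_matches_generator_scales(self):
        calib = default_calibration((6, 10))
        assert set(calib.regions) == {"apoptotic", "intermediate", "non_apoptotic"}
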