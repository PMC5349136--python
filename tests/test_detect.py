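import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.draw import circle_perimeter, disk

from nucleoscan import DetectionParams, ImagePlane, edge_map, hough_circles
from nucleoscan.errors import ParameterError
from nucleoscan.imageio_roi import RegionOfInterest
from nucleoscan.synth import SceneSpec, gen_field
from oracle_utils import brute_force_circles


def _match(dets, row, col, tol=2):
    return [d for d in dets if np.hypot(d.row - row, d.col - col) <= tol]


class TestDetectionParams:
    def test_inverted_radius_range_rejected(self):
        with pytest.raises(ParameterError):
            DetectionParams(radius_min=10, radius_max=5)

    @pytest.mark.parametrize("kw", [
        {"edge_gradient_threshold": 0.0},
        {"sensitivity": 1.0},
        {"min_center_separation": -1},
    ])
    def test_out_of_range_thresholds_rejected(self, kw):
        with pytest.raises(ParameterError):
            DetectionParams(**kw)

    def test_separation_defaults_to_radius_min(self):
        assert DetectionParams(radius_min=6).separation == 6.0


class TestEdgeMap:
    def test_constant_plane_has_no_edges(self):
        edges, _, _ = edge_map(ImagePlane(np.full((32, 32), 0.5)), 0.2)
        assert not edges.any()

    def test_disk_edges_form_ring_near_analytic_circle(self, disk_plane):
        edges, _, _ = edge_map(disk_plane, 0.2)
        ys, xs = np.nonzero(edges)
        pr, pc = circle_perimeter(50, 50, 8)
        d = cdist(np.c_[ys, xs], np.c_[pr, pc])
        hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
        assert hausdorff <= 2.0

    def test_edge_count_monotone_in_threshold(self):
        plane, _ = gen_field(SceneSpec(n_nuclei=10, seed=0))
        lo = edge_map(plane, 0.2)[0].sum()
        hi = edge_map(plane, 0.999)[0].sum()
        assert hi <= lo


class TestHoughCircles:
    def test_single_disk_recovered(self, disk_plane):
        dets = hough_circles(disk_plane, DetectionParams(radius_min=5, radius_max=12))
        assert len(dets) == 1
        assert np.hypot(dets[0].row - 50, dets[0].col - 50) <= 2
        assert abs(dets[0].radius - 8) <= 2

    def test_twelve_separated_disks_all_found(self):
        plane, truth = gen_field(SceneSpec(n_nuclei=12, seed=7))
        dets = hough_circles(plane, DetectionParams())
        assert len(dets) == 12
        for t in truth.nuclei:
            hits = _match(dets, t.row, t.col)
            assert len(hits) == 1
            assert abs(hits[0].radius - t.radius) <= 2

    def test_blank_image_yields_nothing(self):
        assert hough_circles(ImagePlane(np.zeros((64, 64)))) == []

    @pytest.mark.parametrize("param,lo,hi", [
        ("sensitivity", 0.5, 0.9),
        ("edge_gradient_threshold", 0.15, 0.5),
    ])
    def test_detection_count_non_increasing_in_thresholds(self, param, lo, hi):
        plane, _ = gen_field(SceneSpec(n_nuclei=15, seed=11))
        n_lo = len(hough_circles(plane, DetectionParams(**{param: lo})))
        n_hi = len(hough_circles(plane, DetectionParams(**{param: hi})))
        assert n_hi <= n_lo

    @pytest.mark.parametrize("shift", [(5, 0), (0, -7), (9, 4)])
    def test_translation_equivariance(self, shift):
        plane, truth = gen_field(SceneSpec(n_nuclei=6, seed=13))
        base = hough_circles(plane, DetectionParams())
        rolled = ImagePlane(np.roll(plane.pixels, shift, axis=(0, 1)))
        moved = hough_circles(rolled, DetectionParams())
        assert len(moved) == len(base)
        for d in base:
            hits = _match(moved, d.row + shift[0], d.col + shift[1], tol=1)
            assert len(hits) == 1

    def test_roi_gates_detections_and_full_frame_is_identity(self):
        plane, truth = gen_field(SceneSpec(n_nuclei=10, seed=5))
        params = DetectionParams()
        ungated = hough_circles(plane, params)
        full = hough_circles(
            plane, params, roi=RegionOfInterest.full_frame(plane.shape)
        )
        assert [(d.row, d.col) for d in full] == [(d.row, d.col) for d in ungated]
        # half-frame ROI keeps only the nuclei whose centers fall inside
        half = np.zeros(plane.shape, dtype=bool)
        half[:, : plane.width // 2] = True
        gated = hough_circles(plane, params, roi=RegionOfInterest(half, "user polygon"))
        assert all(d.col < plane.width // 2 for d in gated)
        assert len(gated) == sum(1 for d in ungated if d.col < plane.width // 2)

    def test_results_sorted_by_sharpness_then_position(self):
        plane, _ = gen_field(SceneSpec(n_nuclei=10, seed=19))
        dets = hough_circles(plane, DetectionParams())
        keys = [(-d.sharpness, d.row, d.col) for d in dets]
        assert keys == sorted(keys)
        assert all(d.sharpness > 0 for d in dets)


class TestOracleEquivalence:
    """Hough detections must match exhaustive edge-coincidence scoring."""

    @pytest.mark.parametrize("seed", range(5))
    def test_small_fields_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 4))
        img = np.full((64, 64), 0.05)
        centers = [(16, 16), (16, 46), (46, 31)][:n]
        radii = []
        for cy, cx in centers:
            r = int(rng.integers(5, 11))
            radii.append(r)
            rr, cc = disk((cy, cx), r, shape=img.shape)
            img[rr, cc] = 0.7
        img = np.clip(img + rng.normal(0, 0.01, img.shape), 0, 1)
        plane = ImagePlane(img)
        params = DetectionParams(radius_min=4, radius_max=12)
        dets = hough_circles(plane, params)
        oracle = brute_force_circles(plane, params, top_k=n)
        assert len(dets) == len(oracle) == n
        for oy, ox, orad, _ in oracle:
            hits = [
                d for d in dets
                if np.hypot(d.row - oy, d.col - ox) <= 2 and abs(d.radius - orad) <= 2
            ]
            assert len(hits) == 1

    def test_agrees_with_library_hough_on_clean_disk(self, disk_plane):
        """Independent cross-check against scikit-image's circle Hough."""
        from skimage.feature import canny
        from skimage.transform import hough_circle, hough_circle_peaks

        edges = canny(disk_plane.pixels, sigma=1.0)
        radii = np.arange(5, 13)
        h = hough_circle(edges, radii)
        _, cx, cy, rad = hough_circle_peaks(h, radii, total_num_peaks=1)
        ours = hough_circles(disk_plane, DetectionParams(radius_min=5, radius_max=12))
        assert len(ours) == 1
        assert np.hypot(ours[0].row - cy[0], ours[0].col - cx[0]) <= 2
        assert abs(ours[0].radius - rad[0]) <= 2
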