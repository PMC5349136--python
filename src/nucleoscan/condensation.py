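"""Chromatin-condensation scoring of detected nuclei.

Each detected nucleus circle is decomposed into k = 4 intensity clusters
(1-D k-means over pixel intensities). The cluster structure drives a
three-way rule keyed on two quantities:

* ``a`` — area fraction of the brightest cluster inside the circle,
* ``d`` — brightness difference between the brightest and darkest cluster
  centroids, by default *relative*: ``d = (c_max - c_min) / c_max``, so the
  percentage thresholds are invariant to exposure scaling.

Branches:

1. ``a < 0.15`` and ``d >= 0.20`` — the small bright cluster is the
   **nucleolus** (visible only in non-apoptotic nuclei); its pixels are
   excluded from scoring.
2. ``a > 0.15`` and ``d > 0.30`` — the nucleus is **potentially apoptotic**;
   only the brightest cluster is scored.
3. otherwise (intermediate states, noisy images) — the whole circle is
   scored.

From the scored pixel set S the nucleus gets an *effective radius*
``sqrt(|S| / pi)`` and an *intensity* (mean intensity over S, i.e. normalized
intensity per unit area). States — apoptotic / non-apoptotic / intermediate —
are assigned by user-calibrated regions of the (effective radius, intensity)
plane: apoptotic nuclei sit at high intensity and low effective radius,
non-apoptotic at low intensity and high effective radius, intermediate at
higher intensity than non-apoptotic with similar effective radius.

The 15 % / 20 % / 30 % thresholds are configurable defaults chosen by
comparative analysis of apoptotic vs non-apoptotic image libraries; they are
parameters, not constants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk

from .detect import CircleDetection, DetectionParams, hough_circles
from .errors import EmptySampleError, ParameterError
from .imageio_roi import ImagePlane, RegionOfInterest

logger = logging.getLogger(__name__)

STATES = ("apoptotic", "intermediate", "non_apoptotic")
#: deterministic tie-break priority for equidistant calibration regions
STATE_PRIORITY = {"apoptotic": 0, "intermediate": 1, "non_apoptotic": 2}

#: minimum nuclei per sample below which ratios are statistically flimsy
SAMPLE_FLOOR = 200


# ---------------------------------------------------------------------------
# 1-D k-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterDecomposition:
    """k-means decomposition of the pixel intensities inside one circle.

    ``assignments`` are labels in {0..k-1} ordered by ascending centroid;
    ``centroids`` are the cluster mean intensities (strictly increasing);
    ``areas`` the per-cluster pixel counts. ``k`` may be smaller than
    requested when the circle holds fewer distinct intensity values.
    """

    assignments: np.ndarray
    centroids: np.ndarray
    areas: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if int(self.areas.sum()) != len(self.assignments):
            raise ValueError("cluster areas must partition the pixel set")
        if len(self.centroids) > 1 and not np.all(np.diff(self.centroids) > 0):
            raise ValueError("centroids must be strictly increasing")

    @property
    def brightest_area_fraction(self) -> float:
        return float(self.areas[-1]) / float(self.areas.sum())

    def brightness_difference(self, relative: bool = True) -> float:
        c_min, c_max = float(self.centroids[0]), float(self.centroids[-1])
        if relative:
            return (c_max - c_min) / c_max if c_max > 0 else 0.0
        return c_max - c_min


def _kmeans_1d(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal 1-D k-means by dynamic programming over sorted-order splits.

    The optimal 1-D partition is contiguous in sorted order, so DP over split
    points finds the global minimum within-cluster sum of squares. O(k n^2)
    with prefix sums; deterministic — no initialization or restarts.
    Returns (labels, centroids, areas) with clusters ordered by centroid.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    x = values[order]
    # prefix sums for O(1) segment SSE: sse(i, j) over x[i..j] inclusive
    ps = np.concatenate(([0.0], np.cumsum(x)))
    ps2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_sse(i: np.ndarray, j: int) -> np.ndarray:
        cnt = j - i + 1
        s = ps[j + 1] - ps[i]
        return (ps2[j + 1] - ps2[i]) - s * s / cnt

    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=np.intp)
    idx = np.arange(n)
    cost[0] = np.array([seg_sse(np.array([0]), j)[0] for j in range(n)])
    for m in range(1, k):
        for j in range(m, n):
            i = idx[m: j + 1]  # first index of the last cluster
            cand = cost[m - 1][i - 1] + seg_sse(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            split[m, j] = i[best]
    # backtrack boundaries
    bounds = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = int(split[m, j])
        bounds.append(i)
        j = i - 1
    bounds = sorted(bounds)
    labels_sorted = np.zeros(n, dtype=np.intp)
    for b in bounds:
        labels_sorted[b:] += 1
    labels = np.empty(n, dtype=np.intp)
    labels[order] = labels_sorted
    centroids = np.array([x[labels_sorted == m].mean() for m in range(k)])
    areas = np.array([(labels_sorted == m).sum() for m in range(k)])
    return labels, centroids, areas


def _circle_pixel_indices(
    plane: ImagePlane, circle: CircleDetection
) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = draw_disk((circle.row, circle.col), circle.radius, shape=plane.shape)
    return rr, cc


def cluster_nucleus(
    plane: ImagePlane,
    circle: CircleDetection,
    k: int = 4,
    seed: int = 0,
) -> ClusterDecomposition:
    """Decompose the pixels inside a nucleus circle into k intensity clusters.

    Clustering is 1-D k-means over intensities, solved exactly (dynamic
    programming over contiguous splits of the sorted values), hence
    deterministic; ``seed`` is accepted for interface stability but unused.
    If the circle holds fewer than k distinct intensity values, k degrades to
    that number (recorded in the result's ``k``).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    rr, cc = _circle_pixel_indices(plane, circle)
    values = plane.pixels[rr, cc]
    if len(values) < k:
        raise ParameterError(
            f"circle at {circle.center} holds {len(values)} pixels, fewer than k={k}"
        )
    n_distinct = len(np.unique(values))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.info(
            "cluster_nucleus: only %d distinct intensities, degrading k from %d",
            n_distinct, k,
        )
    labels, centroids, areas = _kmeans_1d(values, k_eff)
    return ClusterDecomposition(
        assignments=labels, centroids=centroids, areas=areas, k=k_eff
    )


# ---------------------------------------------------------------------------
# nucleolus / apoptotic-candidate rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CondensationParams:
    """Thresholds of the three-way cluster rule.

    ``brightest_area_threshold`` (default 0.15) splits "small bright cluster"
    (potential nucleolus) from "large bright cluster" (potential condensed
    chromatin); ``nucleolus_min_diff`` (0.20, inclusive) and
    ``apoptotic_min_diff`` (0.30, strict) are the brightness-difference
    thresholds of the two branches. ``relative_difference`` selects whether
    the difference is measured relative to the brightest centroid (default)
    or on the raw intensity scale.
    """

    k: int = 4
    brightest_area_threshold: float = 0.15
    nucleolus_min_diff: float = 0.20
    apoptotic_min_diff: float = 0.30
    relative_difference: bool = True

    def with_overrides(self, **kwargs) -> "CondensationParams":
        return replace(self, **kwargs)


def nucleolus_rule(
    dec: ClusterDecomposition,
    params: CondensationParams | None = None,
) -> str:
    """Decide which pixels of a nucleus are scored.

    Returns one of:

    * ``"nucleolus_removed"`` — brightest-cluster area fraction a < 0.15 and
      brightness difference d >= 0.20: the bright spot is the nucleolus;
      score everything except it.
    * ``"brightest_only"`` — a > 0.15 and d > 0.30: potentially apoptotic;
      score only the brightest cluster.
    * ``"whole_circle"`` — neither condition met (a exactly at the area
      threshold always lands here, both area comparisons being strict).
    """
    params = params or CondensationParams()
    a = dec.brightest_area_fraction
    d = dec.brightness_difference(relative=params.relative_difference)
    if dec.k >= 2 and a < params.brightest_area_threshold and d >= params.nucleolus_min_diff:
        return "nucleolus_removed"
    if dec.k >= 2 and a > params.brightest_area_threshold and d > params.apoptotic_min_diff:
        return "brightest_only"
    return "whole_circle"


@dataclass(frozen=True)
class NucleusMeasurement:
    """Per-nucleus scoring outcome: the two classification coordinates.

    ``effective_radius`` = sqrt(|S| / pi) for the scored pixel set S;
    ``intensity`` = mean intensity over S. ``state`` is filled in by
    :func:`classify`.
    """

    circle: CircleDetection
    effective_radius: float
    intensity: float
    nucleolus_present: bool
    rule_branch: str
    state: str | None = None

    def with_state(self, state: str) -> "NucleusMeasurement":
        return replace(self, state=state)


def measure_nucleus(
    plane: ImagePlane,
    circle: CircleDetection,
    params: CondensationParams | None = None,
    seed: int = 0,
) -> NucleusMeasurement:
    """Cluster one nucleus and compute its effective radius and intensity."""
    params = params or CondensationParams()
    dec = cluster_nucleus(plane, circle, k=params.k, seed=seed)
    branch = nucleolus_rule(dec, params)
    rr, cc = _circle_pixel_indices(plane, circle)
    values = plane.pixels[rr, cc]
    brightest = dec.k - 1
    if branch == "nucleolus_removed":
        scored = values[dec.assignments != brightest]
    elif branch == "brightest_only":
        scored = values[dec.assignments == brightest]
    else:
        scored = values
    if len(scored) == 0:  # pragma: no cover - excluded by branch conditions
        raise RuntimeError("internal error: empty scored pixel set")
    return NucleusMeasurement(
        circle=circle,
        effective_radius=float(np.sqrt(len(scored) / np.pi)),
        intensity=float(scored.mean()),
        nucleolus_present=(branch == "nucleolus_removed"),
        rule_branch=branch,
    )


# ---------------------------------------------------------------------------
# calibration and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateRegion:
    """Axis-aligned rectangle in (effective_radius, intensity) space."""

    r_min: float
    r_max: float
    i_min: float
    i_max: float

    def contains(self, r: float, i: float) -> bool:
        return self.r_min <= r <= self.r_max and self.i_min <= i <= self.i_max

    def distance(self, r: float, i: float, r_scale: float, i_scale: float) -> float:
        dr = max(self.r_min - r, 0.0, r - self.r_max) / r_scale
        di = max(self.i_min - i, 0.0, i - self.i_max) / i_scale
        return float(np.hypot(dr, di))

    def overlaps(self, other: "StateRegion") -> bool:
        return not (
            self.r_max < other.r_min or other.r_max < self.r_min
            or self.i_max < other.i_min or other.i_max < self.i_min
        )


@dataclass(frozen=True)
class CalibrationRegions:
    """User-calibrated partition of (effective_radius, intensity) space.

    One rectangle per state; rectangles must be pairwise disjoint. A point in
    no rectangle resolves to the nearest rectangle in standardized
    coordinates (each axis scaled by the overall calibration span), with ties
    broken apoptotic > intermediate > non_apoptotic.
    """

    regions: dict  # state -> StateRegion

    def __post_init__(self) -> None:
        regions = {
            s: r if isinstance(r, StateRegion) else StateRegion(**r)
            for s, r in self.regions.items()
        }
        if set(regions) != set(STATES):
            raise ValueError(f"calibration needs exactly the states {STATES}")
        names = sorted(regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if regions[a].overlaps(regions[b]):
                    raise ValueError(f"calibration regions {a!r} and {b!r} overlap")
        object.__setattr__(self, "regions", regions)

    @property
    def _scales(self) -> tuple[float, float]:
        rs = [r for reg in self.regions.values() for r in (reg.r_min, reg.r_max)]
        is_ = [i for reg in self.regions.values() for i in (reg.i_min, reg.i_max)]
        return max(max(rs) - min(rs), 1e-9), max(max(is_) - min(is_), 1e-9)

    def to_dict(self) -> dict:
        return {
            s: {"r_min": r.r_min, "r_max": r.r_max, "i_min": r.i_min, "i_max": r.i_max}
            for s, r in self.regions.items()
        }


def default_calibration(radius_range: tuple[int, int] = (6, 10)) -> CalibrationRegions:
    """Calibration regions matching the synthetic generator's defaults.

    Derived from the generator's parameter midpoints: condensed nuclei render
    at ~0.9 intensity with effective radius near sqrt(core_area)*radius, and
    relaxed nuclei at ~0.45 with effective radius near the full circle. Real
    data needs recalibration from a scatter export (see docs/methods.md).
    """
    rmax = float(radius_range[1])
    return CalibrationRegions(
        regions={
            "apoptotic": StateRegion(0.0, 0.75 * rmax, 0.72, 1.0),
            "intermediate": StateRegion(0.40 * rmax, 1.6 * rmax, 0.55, 0.70),
            "non_apoptotic": StateRegion(0.40 * rmax, 1.6 * rmax, 0.0, 0.53),
        }
    )


def classify(
    measurement: NucleusMeasurement, calibration: CalibrationRegions
) -> str:
    """Assign a state to a measured nucleus via the calibration regions."""
    r, i = measurement.effective_radius, measurement.intensity
    containing = [s for s in STATES if calibration.regions[s].contains(r, i)]
    if containing:
        return containing[0]
    r_scale, i_scale = calibration._scales
    dists = {
        s: calibration.regions[s].distance(r, i, r_scale, i_scale) for s in STATES
    }
    best = min(dists.values())
    winners = sorted(
        (s for s, d in dists.items() if np.isclose(d, best, atol=1e-12)),
        key=lambda s: STATE_PRIORITY[s],
    )
    logger.debug(
        "classify: point (r=%.2f, i=%.3f) outside all calibration regions; "
        "nearest region -> %s", r, i, winners[0],
    )
    return winners[0]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CondensationResult:
    """Sample-level condensation outcome."""

    measurements: tuple[NucleusMeasurement, ...]

    @property
    def n_total(self) -> int:
        return len(self.measurements)

    @property
    def n_apoptotic(self) -> int:
        return sum(1 for m in self.measurements if m.state == "apoptotic")

    @property
    def n_intermediate(self) -> int:
        return sum(1 for m in self.measurements if m.state == "intermediate")

    @property
    def n_non_apoptotic(self) -> int:
        return sum(1 for m in self.measurements if m.state == "non_apoptotic")

    @property
    def percent_condensed(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return 100.0 * self.n_apoptotic / self.n_total

    def branch_frequencies(self) -> dict:
        out = {"nucleolus_removed": 0, "brightest_only": 0, "whole_circle": 0}
        for m in self.measurements:
            out[m.rule_branch] += 1
        return out


def condensation_ratio(
    planes: ImagePlane | list[ImagePlane],
    detection: DetectionParams | None = None,
    calibration: CalibrationRegions | None = None,
    params: CondensationParams | None = None,
    roi: RegionOfInterest | None = None,
    seed: int = 0,
) -> CondensationResult:
    """Detect, measure and classify every nucleus; report percent condensed.

    Accepts one plane or a list (a library pooled into one sample). Warns when
    the sample holds fewer than 200 nuclei, the floor below which ratio
    estimates get noisy. Raises :class:`EmptySampleError` when no nucleus is
    detected at all.
    """
    if isinstance(planes, ImagePlane):
        planes = [planes]
    detection = detection or DetectionParams()
    calibration = calibration or default_calibration(
        (detection.radius_min, detection.radius_max)
    )
    params = params or CondensationParams()
    measurements: list[NucleusMeasurement] = []
    for plane in planes:
        for circle in hough_circles(plane, detection, roi=roi):
            m = measure_nucleus(plane, circle, params=params, seed=seed)
            measurements.append(m.with_state(classify(m, calibration)))
    if not measurements:
        raise EmptySampleError("no nuclei detected in the sample")
    if len(measurements) < SAMPLE_FLOOR:
        warnings.warn(
            f"sample holds {len(measurements)} nuclei, below the recommended "
            f"floor of {SAMPLE_FLOOR}; the condensation ratio may be noisy",
            stacklevel=2,
        )
    return CondensationResult(measurements=tuple(measurements))
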