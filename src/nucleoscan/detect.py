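"""Nucleus detection by a Circle Hough Transform (CHT).

Stained nuclei are close enough to circles that circle detection serves as
segmentation. Edge pixels (gradient magnitude above a user threshold, relative
to the image maximum) cast votes along their gradient direction, in both
polarities, at every candidate radius; accumulator peaks become detections.

Two user thresholds control detection, matching the tool's operating
philosophy that one parameter set serves a whole experiment at fixed
magnification:

* ``edge_gradient_threshold`` — fraction of the maximum gradient magnitude a
  pixel needs to count as an edge.
* ``sensitivity`` — acceptance threshold on a candidate circle's perimeter
  support: the fraction of the circle covered by edge pixels at the right
  distance whose gradient points radially. Normalizing by the circle's own
  circumference makes the threshold radius-independent (a clean full circle
  scores ~1 at any radius).

Each detection carries a *sharpness* score: the gradient-weighted mass of
its edge "pointers" — the votes of sharp edges that point to the circle
center from the right distance. Defocus both spreads an edge beyond the
vote ring and weakens its gradient, so the in-focus instance of a nucleus
scores highest; this is what the z-stack de-duplication stage uses to pick
each nucleus's in-focus layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .imageio_roi import ImagePlane, RegionOfInterest


@dataclass(frozen=True)
class DetectionParams:
    """CHT detection parameters.

    radius_min, radius_max : candidate nucleus radii in pixels (inclusive).
    edge_gradient_threshold : fraction of the maximum gradient magnitude, in
        (0, 1); pixels at or above it are edges.
    sensitivity : acceptance threshold in (0, 1) on the perimeter-support
        coverage of a candidate circle (supporting edge pointers normalized
        by the radius circumference).
    min_center_separation : detections with centers closer than this are
        merged, keeping the higher score. Defaults to radius_min (two real
        nuclei can abut, but their centers cannot be closer than one minimal
        radius).
    """

    radius_min: int = 4
    radius_max: int = 13
    edge_gradient_threshold: float = 0.20
    sensitivity: float = 0.70
    min_center_separation: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.radius_min <= self.radius_max):
            raise ParameterError(
                f"need 1 <= radius_min <= radius_max, got "
                f"[{self.radius_min}, {self.radius_max}]"
            )
        for name in ("edge_gradient_threshold", "sensitivity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.min_center_separation is not None and self.min_center_separation <= 0:
            raise ParameterError("min_center_separation must be positive")

    @property
    def separation(self) -> float:
        return (
            float(self.radius_min)
            if self.min_center_separation is None
            else float(self.min_center_separation)
        )

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.radius_max > min(shape) / 2:
            raise ParameterError(
                f"radius_max={self.radius_max} exceeds half the smaller image "
                f"dimension of {shape}"
            )

    def with_overrides(self, **kwargs) -> "DetectionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CircleDetection:
    """One detected nucleus: center (row, col), radius, sharpness, layer.

    ``sharpness`` is the gradient-weighted vote mass of the edge pointers
    supporting the circle. ``layer_index`` is 0 for single-plane input.
    """

    row: int
    col: int
    radius: int
    sharpness: float
    layer_index: int = 0
    score: float = 0.0  # circumference-normalized peak, for diagnostics

    @property
    def center(self) -> tuple[int, int]:
        return (self.row, self.col)

    def distance_to(self, other: "CircleDetection") -> float:
        return float(np.hypot(self.row - other.row, self.col - other.col))


def gradient_magnitude_max(plane: ImagePlane) -> float:
    """Maximum Sobel gradient magnitude of a plane.

    Used to share one edge-threshold scale across the planes of a z-stack:
    within one acquisition the intensity scale is common, and normalizing a
    defocused plane by its own weak maximum would dredge blur and noise up to
    edge status.
    """
    gr = ndimage.sobel(plane.pixels, axis=0, mode="reflect")
    gc = ndimage.sobel(plane.pixels, axis=1, mode="reflect")
    return float(np.hypot(gr, gc).max())


def edge_map(
    plane: ImagePlane,
    edge_gradient_threshold: float = 0.20,
    gradient_ceiling: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold the gradient magnitude into an edge raster.

    Returns ``(edges, grad_row, grad_col)`` where ``edges`` marks pixels whose
    Sobel gradient magnitude is at least ``edge_gradient_threshold`` times the
    maximum magnitude over the plane (or times ``gradient_ceiling`` when
    given, e.g. the stack-wide maximum); the gradient components are retained
    for directed vote casting. A constant image yields an empty edge map.
    """
    if not (0.0 < edge_gradient_threshold < 1.0):
        raise ParameterError("edge_gradient_threshold must be in (0, 1)")
    px = plane.pixels
    gr = ndimage.sobel(px, axis=0, mode="reflect")
    gc = ndimage.sobel(px, axis=1, mode="reflect")
    mag = np.hypot(gr, gc)
    peak = gradient_ceiling if gradient_ceiling is not None else float(mag.max())
    if peak <= 0:
        return np.zeros(px.shape, dtype=bool), gr, gc
    edges = mag >= edge_gradient_threshold * peak
    return edges, gr, gc


def _accumulate(
    edges: np.ndarray, gr: np.ndarray, gc: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Cast gradient-directed votes into a (radius, row, col) accumulator.

    Each edge pixel votes at distance r along +/- its unit gradient, covering
    both bright-on-dark and dark-on-bright circle polarities.
    """
    h, w = edges.shape
    acc = np.zeros((len(radii), h, w), dtype=np.float64)
    ys, xs = np.nonzero(edges)
    if len(ys) == 0:
        return acc
    mag = np.hypot(gr[ys, xs], gc[ys, xs])
    mag[mag == 0] = 1.0
    ur = gr[ys, xs] / mag
    uc = gc[ys, xs] / mag
    for i, r in enumerate(radii):
        for sign in (1.0, -1.0):
            cr = np.rint(ys + sign * r * ur).astype(np.intp)
            cc = np.rint(xs + sign * r * uc).astype(np.intp)
            ok = (cr >= 0) & (cr < h) & (cc >= 0) & (cc < w)
            np.add.at(acc[i], (cr[ok], cc[ok]), 1.0)
    return acc


#: accumulator floor (fraction of the ideal smoothed peak) below which a
#: local maximum is not even considered a candidate circle
CANDIDATE_FLOOR = 0.08

#: radial tolerance (px) and angular alignment for perimeter support
SUPPORT_RADIAL_TOL = 1.0
SUPPORT_MIN_COS = 0.9


def _perimeter_support(
    edges: np.ndarray,
    gr: np.ndarray,
    gc: np.ndarray,
    row: int,
    col: int,
    radius: int,
) -> tuple[float, float, float]:
    """Score a candidate circle by the edge pixels that point to its center.

    An edge pixel supports the circle when it lies at distance radius +/- 1 px
    from the center and its gradient is radially aligned (|cos| >= 0.9, either
    polarity, so both bright-on-dark and dark-on-bright circles qualify).
    Returns ``(coverage, pointers, strength)``: ``pointers`` is the raw count
    of supporting edge pixels, ``coverage`` the fraction of ~2 px angular bins
    around the circle that hold at least one supporter (a full circle scores
    ~1, a stray arc a fraction), and ``strength`` the gradient-magnitude-
    weighted vote mass of the supporters — the sharpness score. Defocus
    spreads an edge and weakens its gradient, so the in-focus instance of a
    nucleus collects the most vote mass inside the +/- 1 px ring.
    """
    h, w = edges.shape
    m = radius + 2
    r0, r1 = max(0, row - m), min(h, row + m + 1)
    c0, c1 = max(0, col - m), min(w, col + m + 1)
    ys, xs = np.nonzero(edges[r0:r1, c0:c1])
    if len(ys) == 0:
        return 0.0, 0.0, 0.0
    ys = ys + r0
    xs = xs + c0
    dy = ys - row
    dx = xs - col
    dist = np.hypot(dy, dx)
    on_ring = np.abs(dist - radius) <= SUPPORT_RADIAL_TOL
    if not on_ring.any():
        return 0.0, 0.0, 0.0
    ys, xs, dy, dx, dist = ys[on_ring], xs[on_ring], dy[on_ring], dx[on_ring], dist[on_ring]
    g_r = gr[ys, xs]
    g_c = gc[ys, xs]
    gmag = np.hypot(g_r, g_c)
    gmag[gmag == 0] = 1.0
    radial_cos = np.abs(dy * g_r + dx * g_c) / (np.maximum(dist, 1e-9) * gmag)
    aligned = radial_cos >= SUPPORT_MIN_COS
    if not aligned.any():
        return 0.0, 0.0, 0.0
    pointers = float(aligned.sum())
    strength = float(gmag[aligned].sum())
    n_bins = max(8, int(round(np.pi * radius)))
    angles = np.arctan2(dy[aligned], dx[aligned])
    bins = np.floor((angles + np.pi) / (2 * np.pi) * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    coverage = len(np.unique(bins)) / n_bins
    return float(coverage), pointers, strength


def hough_circles(
    plane: ImagePlane,
    params: DetectionParams | None = None,
    roi: RegionOfInterest | None = None,
    layer_index: int = 0,
    gradient_ceiling: float | None = None,
) -> list[CircleDetection]:
    """Detect nuclei as circles in one plane.

    Pipeline: edge map -> gradient-directed vote accumulation over the radius
    range -> per-radius Gaussian smoothing (sigma = 1 px) of the accumulator
    -> 3-D local maxima propose candidate circles -> each candidate is
    re-scored by perimeter support (fraction of the circle covered by edge
    pixels whose gradient points to the center, the "sharp edges that point
    to the center" that the sharpness rating counts) -> non-maximum
    suppression at ``min_center_separation`` (and circle containment: the
    boundary of a large circle casts satellite peaks at smaller radii, and a
    peak contained in a stronger peak's circle is the same nucleus) ->
    acceptance at ``sensitivity`` -> ROI gating (centers outside the ROI are
    discarded).

    ``sharpness`` of a detection is the gradient-weighted vote mass of its
    supporting pointers: defocus spreads the edge beyond the vote ring and
    weakens its gradient, so this score ranks focal planes. Results are
    sorted by descending sharpness, ties broken by (row, col).

    ``gradient_ceiling`` overrides the per-plane gradient normalization of
    the edge threshold (used by the z-stack pipeline to share one scale
    across layers).
    """
    params = params or DetectionParams()
    params.validate_for(plane.shape)
    if roi is not None and roi.mask.shape != plane.shape:
        raise ParameterError(
            f"ROI shape {roi.mask.shape} does not match plane shape {plane.shape}"
        )
    edges, gr, gc = edge_map(
        plane, params.edge_gradient_threshold, gradient_ceiling=gradient_ceiling
    )
    radii = np.arange(params.radius_min, params.radius_max + 1)
    acc = _accumulate(edges, gr, gc, radii)
    if not acc.any():
        return []
    acc_sigma = 1.0
    smoothed = ndimage.gaussian_filter(
        acc, sigma=(0, acc_sigma, acc_sigma), mode="constant"
    )
    # Candidate pruning: normalize by the response an ideal circle would
    # produce under the same smoothing (2*pi*r coincident votes smoothed by a
    # 2-D Gaussian peak at r / sigma^2), so the floor is radius-independent.
    norm = smoothed * (acc_sigma**2) / radii[:, None, None]
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (
        (norm == ndimage.maximum_filter(norm, footprint=footprint))
        & (norm >= CANDIDATE_FLOOR)
    )
    ri, yi, xi = np.nonzero(local_max)

    scored = []
    for k in range(len(ri)):
        y, x, r = int(yi[k]), int(xi[k]), int(radii[ri[k]])
        coverage, pointers, strength = _perimeter_support(edges, gr, gc, y, x, r)
        if pointers > 0:
            scored.append((coverage, y, x, r, strength))

    # suppress first, then threshold at sensitivity.
    # Suppression priority: accepted candidates (coverage >= sensitivity)
    # first, larger radii before smaller within them, then coverage. A
    # nucleolus is itself a genuine small bright circle inside its nucleus;
    # preferring the containing circle keeps the nucleus and absorbs the
    # nucleolus ghost (and the satellite rings a large boundary casts at
    # small radii), instead of the other way round.
    scored.sort(
        key=lambda t: (
            t[0] < params.sensitivity,
            -t[3] if t[0] >= params.sensitivity else 0,
            -t[0],
            t[1],
            t[2],
            t[3],
        )
    )
    kept: list[tuple[float, int, int, int, float]] = []
    min_sep = params.separation
    for coverage, y, x, r, sharpness in scored:
        if any(
            (y - ky) ** 2 + (x - kx) ** 2 < max(min_sep, kr, r) ** 2
            for _, ky, kx, kr, _ in kept
        ):
            continue
        kept.append((coverage, y, x, r, sharpness))

    detections = []
    for coverage, y, x, r, sharpness in kept:
        if coverage < params.sensitivity:
            continue
        if roi is not None and not roi.contains(y, x):
            continue
        detections.append(
            CircleDetection(
                row=y, col=x, radius=r, sharpness=sharpness,
                layer_index=layer_index, score=coverage,
            )
        )
    detections.sort(key=lambda d: (-d.sharpness, d.row, d.col))
    return detections


def detections_to_records(detections: list[CircleDetection], image: str = "") -> list[dict]:
    """Flatten detections for CSV export."""
    return [
        {
            "image": image,
            "layer_index": d.layer_index,
            "row": d.row,
            "col": d.col,
            "radius_px": d.radius,
            "sharpness": d.sharpness,
        }
        for d in detections
    ]
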