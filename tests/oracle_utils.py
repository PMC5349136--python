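"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: circle scoring is
exhaustive edge-coincidence counting over every (center, radius) triple, and
1-D clustering is exhaustive enumeration of contiguous splits of the sorted
values.
"""

from __future__ import annotations

import itertools

import numpy as np

from nucleoscan.detect import DetectionParams, edge_map
from nucleoscan.imageio_roi import ImagePlane


def brute_force_circles(
    plane: ImagePlane, params: DetectionParams, top_k: int
) -> list[tuple[int, int, int, float]]:
    """Exhaustively score every (center, radius) triple by edge coincidence.

    The score of a candidate is the number of edge pixels at distance
    radius +/- 1 from its center, normalized by the circumference. Returns
    the ``top_k`` peaks after greedy suppression (no two peaks closer than
    the larger of their radii / the minimum separation), as
    (row, col, radius, score) tuples.
    """
    edges, _, _ = edge_map(plane, params.edge_gradient_threshold)
    ys, xs = np.nonzero(edges)
    if len(ys) == 0:
        return []
    h, w = edges.shape
    grid_r, grid_c = np.mgrid[0:h, 0:w]
    candidates = []
    for r in range(params.radius_min, params.radius_max + 1):
        # distance of every pixel to every edge pixel, one radius at a time
        d = np.sqrt(
            (grid_r.ravel()[:, None] - ys[None, :]) ** 2
            + (grid_c.ravel()[:, None] - xs[None, :]) ** 2
        )
        counts = (np.abs(d - r) <= 1.0).sum(axis=1)
        score = counts / (2 * np.pi * r)
        for flat_idx in np.nonzero(counts > 0)[0]:
            candidates.append(
                (float(score[flat_idx]), flat_idx // w, flat_idx % w, r)
            )
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    kept: list[tuple[int, int, int, float]] = []
    for score, cy, cx, r in candidates:
        if any(
            (cy - ky) ** 2 + (cx - kx) ** 2 < max(params.separation, kr, r) ** 2
            for ky, kx, kr, _ in kept
        ):
            continue
        kept.append((cy, cx, r, score))
        if len(kept) == top_k:
            break
    return kept


def exhaustive_kmeans_sse(values: np.ndarray, k: int) -> float:
    """Minimum within-cluster SSE over all contiguous splits of sorted values.

    Enumerates every way to place k-1 boundaries in the sorted sequence
    (the optimal 1-D partition is always contiguous in sorted order).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def sse(seg: np.ndarray) -> float:
        return float(((seg - seg.mean()) ** 2).sum())

    best = np.inf
    for bounds in itertools.combinations(range(1, n), k - 1):
        edges_ = (0, *bounds, n)
        total = sum(sse(x[a:b]) for a, b in zip(edges_[:-1], edges_[1:]))
        best = min(best, total)
    return best


def partition_sse(values: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster SSE of a given labelling."""
    total = 0.0
    for lbl in np.unique(labels):
        seg = values[labels == lbl]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total
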