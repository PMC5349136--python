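"""Z-stack de-duplication: count each nucleus once, at its sharpest layer.

Not all nuclei of a hyphal compartment are in focus in any single focal
plane, so nuclei are detected per layer and the same physical nucleus appears
in several adjacent layers at nearly the same (row, col). Detections in
adjacent layers whose centers fall within a linkage distance are grouped
(transitively, so a nucleus visible in three or more sections forms one
group), and only the group member with the highest Hough sharpness score is
counted — the vote count peaks in the layer where the nucleus edge is
sharpest, so that member identifies the in-focus section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import (
    CircleDetection,
    DetectionParams,
    gradient_magnitude_max,
    hough_circles,
)
from .errors import ParameterError
from .imageio_roi import RegionOfInterest, ZStack


@dataclass(frozen=True)
class LayerCountResult:
    """Outcome of counting a stack.

    ``kept`` holds exactly one detection per distinct nucleus, assigned to its
    sharpest layer; ``per_layer_counts[l]`` is the number of kept detections
    whose sharpest layer is ``l``.
    """

    kept: tuple[CircleDetection, ...]
    per_layer_counts: tuple[int, ...]
    discarded_duplicates: int

    @property
    def total_nuclei(self) -> int:
        return len(self.kept)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def link_across_layers(
    per_layer_detections: list[list[CircleDetection]],
    link_distance: float,
) -> list[list[CircleDetection]]:
    """Group detections of the same nucleus across adjacent layers.

    Two detections in *adjacent* layers belong to the same group iff their
    center distance is <= ``link_distance``; groups are the transitive closure
    of such links (strict adjacency: layers 0 and 2 never link directly). If
    transitivity would place two detections of one layer in the same group,
    all but the sharpest of them are split back into singleton groups — one
    physical nucleus yields at most one detection per layer.
    """
    if link_distance <= 0:
        raise ParameterError("link_distance must be positive")
    flat: list[CircleDetection] = [d for layer in per_layer_detections for d in layer]
    uf = _UnionFind(len(flat))
    # index ranges per layer within flat
    offsets = np.cumsum([0] + [len(layer) for layer in per_layer_detections])
    for l in range(len(per_layer_detections) - 1):
        a, b = per_layer_detections[l], per_layer_detections[l + 1]
        for i, da in enumerate(a):
            for j, db in enumerate(b):
                if da.distance_to(db) <= link_distance:
                    uf.union(offsets[l] + i, offsets[l + 1] + j)
    groups: dict[int, list[CircleDetection]] = {}
    for idx, det in enumerate(flat):
        groups.setdefault(uf.find(idx), []).append(det)

    out: list[list[CircleDetection]] = []
    for members in groups.values():
        by_layer: dict[int, list[CircleDetection]] = {}
        for d in members:
            by_layer.setdefault(d.layer_index, []).append(d)
        core, split = [], []
        for same_layer in by_layer.values():
            same_layer.sort(key=lambda d: (-d.sharpness, d.row, d.col))
            core.append(same_layer[0])
            split.extend(same_layer[1:])
        out.append(core)
        out.extend([d] for d in split)
    # deterministic group order: by (layer, row, col) of the sharpest member
    out.sort(key=lambda g: min((d.layer_index, d.row, d.col) for d in g))
    return out


def count_stack(
    stack: ZStack,
    params: DetectionParams | None = None,
    link_distance: float | None = None,
    roi: RegionOfInterest | None = None,
) -> LayerCountResult:
    """Count nuclei in a z-stack, de-duplicated across focal planes.

    Runs the circle detector on every plane, links detections across adjacent
    layers, and keeps one detection per group: the one with maximal sharpness
    (ties broken toward the lower layer index). ``link_distance`` defaults to
    ``params.radius_min`` — centers of the same nucleus drift little between
    0.3 µm sections, and one minimal radius is the only length scale at hand.
    """
    params = params or DetectionParams()
    if len(stack) < 1:
        raise ParameterError("stack must contain at least one plane")
    if link_distance is None:
        link_distance = float(params.radius_min)
    # one gradient scale for the whole stack: a defocused plane normalized by
    # its own weak maximum would promote blur and noise to edges
    ceiling = max(gradient_magnitude_max(p) for p in stack.planes)
    per_layer = [
        hough_circles(plane, params, roi=roi, layer_index=i, gradient_ceiling=ceiling)
        for i, plane in enumerate(stack.planes)
    ]
    groups = link_across_layers(per_layer, link_distance)
    kept = []
    discarded = 0
    for g in groups:
        g_sorted = sorted(g, key=lambda d: (-d.sharpness, d.layer_index))
        kept.append(g_sorted[0])
        discarded += len(g) - 1
    kept.sort(key=lambda d: (d.layer_index, d.row, d.col))
    per_layer_counts = [0] * len(stack)
    for d in kept:
        per_layer_counts[d.layer_index] += 1
    return LayerCountResult(
        kept=tuple(kept),
        per_layer_counts=tuple(per_layer_counts),
        discarded_duplicates=discarded,
    )
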