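"""TUNEL-positive nucleus ratio from DAPI/GFP channel pairs.

TUNEL staining marks DNA strand breaks; imaged in the GFP channel it labels
only apoptotic nuclei, while the DAPI channel labels every nucleus of the same
field. The two acquisitions are offset by a small unknown translation, so the
pair is first registered (intensity-based, translation only), nuclei are
detected independently in both channels, and each GFP detection is verified
against a DAPI counterpart — every real nucleus must appear in DAPI, so an
unpaired GFP detection is a false detection and is excluded. The TUNEL ratio
is the verified GFP count over the DAPI count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detect import (
    CircleDetection,
    DetectionParams,
    gradient_magnitude_max,
    hough_circles,
)
from .errors import EmptySampleError, ParameterError, ShapeMismatchError
from .imageio_roi import ImagePlane

logger = logging.getLogger(__name__)

#: normalized-correlation floor under which registration is declared failed
CORRELATION_FLOOR = 0.1


@dataclass(frozen=True)
class ChannelPair:
    """A DAPI/GFP image pair of one field, with its estimated shift.

    ``estimated_shift`` is the integer (drow, dcol) such that rolling the
    DAPI plane by it best overlays the GFP plane; (0, 0) before registration.
    """

    dapi: ImagePlane
    gfp: ImagePlane
    estimated_shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.dapi.shape != self.gfp.shape:
            raise ShapeMismatchError(
                f"DAPI shape {self.dapi.shape} != GFP shape {self.gfp.shape}"
            )


@dataclass(frozen=True)
class TunelResult:
    """Sample-level TUNEL outcome."""

    n_dapi: int
    n_matched_gfp: int
    n_rejected_gfp: int
    shift: tuple[int, int]
    registration_ok: bool

    @property
    def percent_tunel(self) -> float:
        if self.n_dapi == 0:
            return float("nan")
        return 100.0 * self.n_matched_gfp / self.n_dapi


def register_translation(
    dapi: ImagePlane, gfp: ImagePlane, max_shift: int = 16
) -> tuple[tuple[int, int], float, bool]:
    """Estimate the integer translation between a DAPI/GFP pair.

    Finds the shift (drow, dcol), |drow|,|dcol| <= max_shift, maximizing the
    normalized cross-correlation between the mean-subtracted planes, computed
    with circular (FFT) correlation so wrapped planted shifts are recovered
    exactly. Returns ``(shift, peak, ok)``: when the correlation peak falls
    below 0.1 the channels share too little structure to register, a warning
    is logged and (0, 0) is used.
    """
    if dapi.shape != gfp.shape:
        raise ShapeMismatchError("planes must be congruent for registration")
    h, w = dapi.shape
    if not (0 < max_shift < min(h, w) / 4):
        raise ParameterError("max_shift must be positive and < min(h, w)/4")
    a = dapi.pixels - dapi.pixels.mean()
    b = gfp.pixels - gfp.pixels.mean()
    denom = a.std() * b.std() * a.size
    if denom == 0:
        logger.warning("register_translation: constant channel, using shift (0, 0)")
        return (0, 0), 0.0, False
    # corr[dr, dc] = sum_x a[x + d] * b[x]  -> peak where roll(dapi, d) matches gfp
    corr = np.real(np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b))) / denom
    shifts = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(shifts % h, shifts % w)]
    peak_idx = np.unravel_index(np.argmax(window), window.shape)
    peak = float(window[peak_idx])
    shift = (int(shifts[peak_idx[0]]), int(shifts[peak_idx[1]]))
    if peak < CORRELATION_FLOOR:
        logger.warning(
            "register_translation: correlation peak %.3f below %.1f, "
            "registration failed, using shift (0, 0)", peak, CORRELATION_FLOOR,
        )
        return (0, 0), peak, False
    return shift, peak, True


def align_pair(
    dapi: ImagePlane, gfp: ImagePlane, max_shift: int = 16
) -> tuple[ChannelPair, bool]:
    """Register a pair and return it with the GFP plane shifted into the
    DAPI frame (circular shift; detections near the wrapped border are the
    caller's concern, shifts being small relative to the field). The second
    element reports whether registration succeeded."""
    shift, _, ok = register_translation(dapi, gfp, max_shift=max_shift)
    aligned = np.roll(gfp.pixels, (-shift[0], -shift[1]), axis=(0, 1))
    gfp_aligned = ImagePlane(
        pixels=aligned, channel_label=gfp.channel_label,
        source_path=gfp.source_path,
    )
    return ChannelPair(dapi=dapi, gfp=gfp_aligned, estimated_shift=shift), ok


def match_channels(
    dapi_detections: list[CircleDetection],
    gfp_detections: list[CircleDetection],
    match_distance: float,
) -> tuple[list[tuple[CircleDetection, CircleDetection]], list[CircleDetection]]:
    """Verify GFP detections against DAPI centers, one-to-one.

    Candidate pairs are taken in ascending center-distance order; a GFP
    detection is verified iff an unclaimed DAPI detection lies within
    ``match_distance``. Returns (matched pairs, rejected GFP detections).
    """
    if match_distance <= 0:
        raise ParameterError("match_distance must be positive")
    pairs = [
        (g.distance_to(d), i, j)
        for i, d in enumerate(dapi_detections)
        for j, g in enumerate(gfp_detections)
        if g.distance_to(d) <= match_distance
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_g: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_d or j in used_g:
            continue
        used_d.add(i)
        used_g.add(j)
        matched.append((dapi_detections[i], gfp_detections[j]))
    rejected = [g for j, g in enumerate(gfp_detections) if j not in used_g]
    return matched, rejected


def tunel_ratio(
    dapi: ImagePlane,
    gfp: ImagePlane,
    params: DetectionParams | None = None,
    gfp_params: DetectionParams | None = None,
    match_distance: float | None = None,
    max_shift: int = 16,
) -> TunelResult:
    """Full TUNEL pipeline: register, detect in both channels, match, ratio.

    The GFP channel reuses the DAPI detection parameters unless
    ``gfp_params`` overrides them (one parameter set per experiment).
    ``match_distance`` defaults to ``params.radius_min``.
    """
    params = params or DetectionParams()
    if match_distance is None:
        match_distance = float(params.radius_min)
    pair, reg_ok = align_pair(dapi, gfp, max_shift=max_shift)
    # one gradient scale for both channels of the field: a TUNEL-negative
    # (near-blank) GFP channel normalized by its own noise maximum would
    # dredge false edges
    ceiling = max(
        gradient_magnitude_max(pair.dapi), gradient_magnitude_max(pair.gfp)
    )
    dapi_dets = hough_circles(pair.dapi, params, gradient_ceiling=ceiling)
    gfp_dets = hough_circles(pair.gfp, gfp_params or params, gradient_ceiling=ceiling)
    if not dapi_dets:
        raise EmptySampleError("no nuclei detected in the DAPI channel")
    matched, rejected = match_channels(dapi_dets, gfp_dets, match_distance)
    return TunelResult(
        n_dapi=len(dapi_dets),
        n_matched_gfp=len(matched),
        n_rejected_gfp=len(rejected),
        shift=pair.estimated_shift,
        registration_ok=reg_ok,
    )
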