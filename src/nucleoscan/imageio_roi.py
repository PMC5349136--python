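"""Image / z-stack input-output and regions of interest.

Fluorescence micrographs arrive as 8- or 16-bit TIFF or PNG files, either
single-channel or RGB. All downstream analysis runs on a single color plane
normalized to [0, 1]: RGB inputs yield exactly the requested channel, never a
luminance mix, because DNA dyes (DAPI / Hoechst 33342) live in the blue channel
and TUNEL signal in the green one. Z-stacks are multi-page TIFFs or directories
of congruent single images ordered bottom to top.

Regions of interest restrict analysis to hyphal areas: either a user polygon
or an automatic hyphal-contour mask (Otsu threshold + morphological closing +
small-object removal).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage import morphology
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from .errors import ChannelError, ShapeMismatchError

logger = logging.getLogger(__name__)

#: channel selector -> index into the last axis of an RGB(A) array
_RGB_INDEX = {"r": 0, "g": 1, "b": 2}

#: semantic labels carried by ImagePlane
CHANNEL_LABELS = ("dapi", "hoechst", "gfp", "gray")


@dataclass(frozen=True)
class ImagePlane:
    """A single-channel 2-D intensity raster normalized to [0, 1].

    The universal input of every analysis stage. ``pixels`` is float64 in
    [0, 1]; normalization divides by the bit-depth maximum of the source, so a
    constant image stays constant and the maximum representable intensity maps
    to exactly 1.0.
    """

    pixels: np.ndarray
    channel_label: str = "gray"
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"ImagePlane needs a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"ImagePlane must be at least 8x8, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("ImagePlane intensities must lie in [0, 1]")
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(
                f"channel_label must be one of {CHANNEL_LABELS}, got {self.channel_label!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ZStack:
    """An ordered series of congruent planes at successive focal depths.

    ``z_step`` is the physical section spacing in µm and is metadata only; no
    computation depends on it.
    """

    planes: tuple[ImagePlane, ...]
    z_step: float = 0.3

    def __post_init__(self) -> None:
        planes = tuple(self.planes)
        if len(planes) < 1:
            raise ValueError("ZStack needs at least one plane")
        shape = planes[0].shape
        label = planes[0].channel_label
        for i, p in enumerate(planes):
            if p.shape != shape:
                raise ShapeMismatchError(
                    f"plane {i} has shape {p.shape}, expected {shape}"
                )
            if p.channel_label != label:
                raise ValueError("all planes of a stack must share a channel label")
        object.__setattr__(self, "planes", planes)

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Boolean mask restricting analysis to hyphal areas.

    ``origin`` records provenance: "user polygon", "auto hyphal contour" or
    "full frame".
    """

    mask: np.ndarray
    origin: str = "full frame"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not m.any():
            raise ValueError("ROI mask must contain at least one true pixel")
        object.__setattr__(self, "mask", m)

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "RegionOfInterest":
        return cls(np.ones(shape, dtype=bool), origin="full frame")

    def contains(self, row: int, col: int) -> bool:
        r, c = int(round(row)), int(round(col))
        if not (0 <= r < self.mask.shape[0] and 0 <= c < self.mask.shape[1]):
            return False
        return bool(self.mask[r, c])


def _dtype_max(arr: np.ndarray) -> float:
    """Bit-depth maximum used for max-preserving normalization."""
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    # float images are assumed to already be on a [0, 1] scale
    return 1.0


def _select_channel(raw: np.ndarray, channel: str, path: str) -> np.ndarray:
    if raw.ndim == 2:
        if channel in _RGB_INDEX:
            raise ChannelError(
                f"{path}: requested color channel {channel!r} from a single-channel image"
            )
        return raw
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        if channel in _RGB_INDEX:
            return raw[..., _RGB_INDEX[channel]]
        raise ChannelError(
            f"{path}: image is RGB; pass channel='r', 'g' or 'b' "
            "(a luminance mix is never computed)"
        )
    raise IOError(f"{path}: unsupported image layout with shape {raw.shape}")


def _label_for(channel: str) -> str:
    return {"b": "dapi", "g": "gfp"}.get(channel, "gray")


def read_image(
    path: str | os.PathLike,
    channel: str = "auto",
    channel_label: str | None = None,
) -> ImagePlane:
    """Read a TIFF/PNG micrograph and extract one color plane on [0, 1].

    Parameters
    ----------
    path : path to a single-page TIFF or PNG, grayscale or RGB, 8/16-bit.
    channel : one of "r", "g", "b", "gray" or "auto". "auto" and "gray"
        accept single-channel input as-is; color channels require RGB input.
    channel_label : semantic label override ("dapi", "hoechst", "gfp", "gray").
        Defaults to "dapi" for the blue channel, "gfp" for green, else "gray".
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read image {path}: {exc}") from exc
    if channel == "auto":
        channel = "gray"
    plane = _select_channel(np.asarray(raw), channel, str(path))
    pixels = plane.astype(np.float64) / _dtype_max(plane)
    return ImagePlane(
        pixels=np.clip(pixels, 0.0, 1.0),
        channel_label=channel_label or _label_for(channel),
        source_path=str(path),
    )


def write_image(path: str | os.PathLike, plane: ImagePlane, bit_depth: int = 16) -> None:
    """Write a plane as an 8- or 16-bit grayscale TIFF/PNG.

    Intensities are scaled by ``2**bit_depth - 1`` and rounded, so a
    read-back differs from the original by at most one quantization step.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = np.rint(plane.pixels * scale).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quantized)
    else:
        iio.imwrite(path, quantized)


def read_zstack(
    path: str | os.PathLike,
    channel: str = "auto",
    z_step: float = 0.3,
    channel_label: str | None = None,
) -> ZStack:
    """Read a z-stack from a multi-page TIFF or a directory of images.

    Planes are ordered by page order (multi-page TIFF) or lexical filename
    order (directory). All pages must be congruent in shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise IOError(f"no TIFF/PNG files found in directory {path}")
        planes = [read_image(f, channel=channel, channel_label=channel_label) for f in files]
        shape = planes[0].shape
        for f, p in zip(files, planes):
            if p.shape != shape:
                raise ShapeMismatchError(
                    f"{f}: shape {p.shape} does not match first plane shape {shape}"
                )
        return ZStack(planes=tuple(planes), z_step=z_step)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read z-stack {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2 or (pages.ndim == 3 and pages.shape[-1] in (3, 4)):
        pages = pages[None, ...]
    planes = []
    for i, page in enumerate(pages):
        if channel == "auto":
            sel = "gray"
        else:
            sel = channel
        plane_px = _select_channel(page, sel, f"{path}[page {i}]")
        if i > 0 and plane_px.shape != planes[0].shape:
            raise ShapeMismatchError(
                f"{path}: page {i} has shape {plane_px.shape}, "
                f"expected {planes[0].shape}"
            )
        planes.append(
            ImagePlane(
                pixels=np.clip(plane_px.astype(np.float64) / _dtype_max(plane_px), 0, 1),
                channel_label=channel_label or _label_for(sel),
                source_path=f"{path}[{i}]",
            )
        )
    return ZStack(planes=tuple(planes), z_step=z_step)


def write_zstack(path: str | os.PathLike, stack: ZStack, bit_depth: int = 16) -> None:
    """Write a stack as a multi-page grayscale TIFF."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    pages = np.stack([np.rint(p.pixels * scale).astype(dtype) for p in stack.planes])
    tifffile.imwrite(Path(path), pages)


def hyphal_contour_mask(
    plane: ImagePlane,
    threshold_method: str = "otsu",
    min_object_px: int = 64,
    fixed_threshold: float = 0.1,
    closing_radius: int = 2,
) -> RegionOfInterest:
    """Segment the hyphal area of a plane into an ROI mask.

    Foreground = pixels above threshold, after morphological closing with a
    disk of ``closing_radius`` px, with connected components smaller than
    ``min_object_px`` removed. If nothing survives (blank or contrast-free
    field), the full frame is returned with a warning so downstream counting
    degrades gracefully rather than failing.
    """
    if min_object_px < 1:
        raise ValueError("min_object_px must be >= 1")
    px = plane.pixels
    if threshold_method == "otsu":
        if np.allclose(px.max(), px.min()):
            logger.warning(
                "hyphal_contour_mask: constant image, falling back to full frame"
            )
            return RegionOfInterest.full_frame(plane.shape)
        thresh = threshold_otsu(px)
    elif threshold_method == "fixed":
        thresh = fixed_threshold
    else:
        raise ValueError("threshold_method must be 'otsu' or 'fixed'")
    fg = px > thresh
    fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = morphology.remove_small_objects(fg, max_size=min_object_px - 1)
    if not fg.any():
        logger.warning(
            "hyphal_contour_mask: no foreground object survived, "
            "falling back to full frame"
        )
        return RegionOfInterest.full_frame(plane.shape)
    return RegionOfInterest(mask=fg, origin="auto hyphal contour")


def polygon_roi(
    shape: tuple[int, int], vertices: Sequence[tuple[float, float]]
) -> RegionOfInterest:
    """Build an ROI from a user polygon given as (row, col) vertices."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask[rr, cc] = True
    if not mask.any():
        raise ValueError("polygon does not cover any pixel of the frame")
    return RegionOfInterest(mask=mask, origin="user polygon")


def load_polygon_roi(path: str | os.PathLike, shape: tuple[int, int]) -> RegionOfInterest:
    """Load a polygon ROI from a JSON file holding a list of [row, col] pairs."""
    with open(path) as fh:
        vertices = json.load(fh)
    return polygon_roi(shape, vertices)
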