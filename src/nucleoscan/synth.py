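"""Seeded synthetic micrographs with full ground truth.

Real image libraries of stained *Botrytis*-like hyphae are not
redistributable, so every stage of the pipeline is exercised against rendered
scenes whose ground truth (centers, radii, chromatin state, in-focus layer,
TUNEL flag, hypha mask) is known exactly.

Morphologies emulated:

* **relaxed** (non-apoptotic) nuclei — a disk of moderate intensity with a
  small, bright nucleolus sub-disk (default 8 % of the area at twice the body
  intensity), the morphology of loosely, evenly stained chromatin with a
  visible nucleolus;
* **condensed** (apoptotic) nuclei — a compact, uniformly bright core on a
  dim halo: high intensity concentrated in a small effective radius.

Z-stacks render each nucleus maximally sharp in its assigned layer and
Gaussian-blurred elsewhere with sigma proportional to the layer distance,
mimicking defocus across 0.3 µm sections. TUNEL pairs share a field: the DAPI
plane carries all nuclei, the GFP plane only the TUNEL-positive subset,
globally translated by a planted integer shift (applied with wrap-around so
shift recovery is exact by construction).

Noise is Poisson shot noise plus Gaussian read noise, the standard
fluorescence camera model. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

from .errors import SceneSpecError
from .imageio_roi import ImagePlane, ZStack


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults describe a typical 400x-1000x field: a horizontal hyphal band
    crossing the frame, nuclei of 6-10 px radius, mild camera noise.
    """

    shape: tuple[int, int] = (256, 384)
    n_nuclei: int = 20
    radius_range: tuple[int, int] = (6, 10)
    condensed_fraction: float = 0.0
    tunel_fraction: float = 0.0
    # relaxed morphology
    body_intensity: float = 0.45
    nucleolus_area_fraction: float = 0.08
    nucleolus_contrast: float = 2.0
    # condensed morphology
    condensed_intensity: float = 0.90
    halo_intensity: float = 0.20
    core_area_fraction: float = 0.40
    # z-stack rendering
    n_layers: int = 1
    defocus_sigma_per_layer: float = 2.0
    # scene / camera
    background: float = 0.03
    hypha_level: float = 0.10
    hypha_band_width: int = 96
    photons: float = 1500.0
    read_noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("condensed_fraction", "tunel_fraction",
                     "nucleolus_area_fraction", "core_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SceneSpecError(f"{name} must be in [0, 1], got {v}")
        if self.n_nuclei < 0:
            raise SceneSpecError("n_nuclei must be >= 0")
        if self.n_layers < 1:
            raise SceneSpecError("n_layers must be >= 1")
        rmin, rmax = self.radius_range
        if not (1 <= rmin <= rmax):
            raise SceneSpecError(f"invalid radius_range {self.radius_range}")
        if rmax * 4 > min(self.shape):
            raise SceneSpecError("radius_range too large for the frame")

    def with_overrides(self, **kwargs) -> "SceneSpec":
        return replace(self, **kwargs)


@dataclass
class NucleusTruth:
    """Ground truth for one planted nucleus."""

    row: int
    col: int
    radius: int
    state: str  # "relaxed" | "condensed"
    sharp_layer: int = 0
    tunel_positive: bool = False


@dataclass
class GroundTruth:
    """Ground truth of a rendered scene: one record per planted nucleus."""

    nuclei: list[NucleusTruth]
    hypha_mask: np.ndarray
    shift: tuple[int, int] = (0, 0)  # planted DAPI->GFP translation

    @property
    def n(self) -> int:
        return len(self.nuclei)

    @property
    def n_condensed(self) -> int:
        return sum(1 for t in self.nuclei if t.state == "condensed")

    @property
    def n_tunel(self) -> int:
        return sum(1 for t in self.nuclei if t.tunel_positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": t.row, "col": t.col, "radius": t.radius,
                    "state": t.state, "sharp_layer": t.sharp_layer,
                    "tunel_positive": t.tunel_positive,
                }
                for t in self.nuclei
            ]
        )


def _band_mask(spec: SceneSpec) -> np.ndarray:
    h, w = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    half = spec.hypha_band_width // 2
    mask[max(0, h // 2 - half): min(h, h // 2 + half), :] = True
    return mask


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Jittered-grid placement inside the hyphal band.

    Grid spacing of 2*radius_max + 3 guarantees the non-overlap contract
    (centers at least 2*radius_max apart) that ground-truth matching relies
    on; cells are shuffled and jittered so fields differ between seeds.
    """
    h, w = spec.shape
    rmax = spec.radius_range[1]
    spacing = 2 * rmax + 3
    jitter = 1
    margin = rmax + 2
    half = spec.hypha_band_width // 2
    r0, r1 = max(h // 2 - half + margin, margin), min(h // 2 + half - margin, h - margin)
    cells = [
        (r, c)
        for r in range(r0, r1 + 1, spacing)
        for c in range(margin, w - margin, spacing)
    ]
    if spec.n_nuclei > len(cells):
        raise SceneSpecError(
            f"cannot pack {spec.n_nuclei} non-overlapping nuclei into this "
            f"frame (capacity {len(cells)})"
        )
    rng.shuffle(cells)
    return [
        (int(r + rng.integers(-jitter, jitter + 1)),
         int(c + rng.integers(-jitter, jitter + 1)))
        for r, c in cells[: spec.n_nuclei]
    ]


def _make_truth(spec: SceneSpec, rng: np.random.Generator) -> GroundTruth:
    centers = _place_centers(spec, rng)
    n = spec.n_nuclei
    n_cond = int(round(spec.condensed_fraction * n))
    n_tun = int(round(spec.tunel_fraction * n))
    states = ["condensed"] * n_cond + ["relaxed"] * (n - n_cond)
    rng.shuffle(states)
    tunel_flags = np.zeros(n, dtype=bool)
    tunel_flags[rng.permutation(n)[:n_tun]] = True
    nuclei = [
        NucleusTruth(
            row=r, col=c,
            radius=int(rng.integers(spec.radius_range[0], spec.radius_range[1] + 1)),
            state=s,
            sharp_layer=int(rng.integers(0, spec.n_layers)),
            tunel_positive=bool(t),
        )
        for (r, c), s, t in zip(centers, states, tunel_flags)
    ]
    return GroundTruth(nuclei=nuclei, hypha_mask=_band_mask(spec))


def _render_nucleus(spec: SceneSpec, t: NucleusTruth,
                    rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Render one nucleus into its own patch; returns (patch, patch_radius)."""
    pr = t.radius + 4
    size = 2 * pr + 1
    patch = np.zeros((size, size))
    center = (pr, pr)
    if t.state == "condensed":
        rr, cc = draw_disk(center, t.radius, shape=patch.shape)
        patch[rr, cc] = spec.halo_intensity
        core_r = np.sqrt(spec.core_area_fraction) * t.radius
        rr, cc = draw_disk(center, core_r, shape=patch.shape)
        patch[rr, cc] = spec.condensed_intensity
    else:
        rr, cc = draw_disk(center, t.radius, shape=patch.shape)
        patch[rr, cc] = spec.body_intensity
        nuc_r = np.sqrt(spec.nucleolus_area_fraction) * t.radius
        # nucleolus sits off-center, fully inside the body
        ang = rng.uniform(0, 2 * np.pi)
        off = 0.35 * t.radius
        nc = (pr + off * np.sin(ang), pr + off * np.cos(ang))
        rr, cc = draw_disk(nc, nuc_r, shape=patch.shape)
        patch[rr, cc] = min(1.0, spec.nucleolus_contrast * spec.body_intensity)
    return patch, pr


def _composite(canvas: np.ndarray, patch: np.ndarray, row: int, col: int, pr: int) -> None:
    h, w = canvas.shape
    r0, r1 = row - pr, row + pr + 1
    c0, c1 = col - pr, col + pr + 1
    pr0, pc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(h, r1), min(w, c1)
    view = canvas[r0:r1, c0:c1]
    pv = patch[pr0: pr0 + (r1 - r0), pc0: pc0 + (c1 - c0)]
    np.maximum(view, pv, out=view)


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    noisy = rng.poisson(np.clip(img, 0, 1) * spec.photons) / spec.photons
    noisy = noisy + rng.normal(0.0, spec.read_noise_sigma, img.shape)
    return np.clip(noisy, 0.0, 1.0)


def _scene_base(spec: SceneSpec, truth: GroundTruth) -> np.ndarray:
    img = np.full(spec.shape, spec.background)
    img[truth.hypha_mask] = spec.hypha_level
    return img


def gen_field(spec: SceneSpec) -> tuple[ImagePlane, GroundTruth]:
    """Render a single-plane field of nuclei with ground truth."""
    rng = np.random.default_rng(spec.seed)
    truth = _make_truth(spec, rng)
    img = _scene_base(spec, truth)
    for t in truth.nuclei:
        patch, pr = _render_nucleus(spec, t, rng)
        _composite(img, patch, t.row, t.col, pr)
    img = _apply_noise(img, spec, rng)
    return ImagePlane(pixels=img, channel_label="dapi", source_path="synthetic"), truth


def gen_zstack(spec: SceneSpec) -> tuple[ZStack, GroundTruth]:
    """Render a z-stack: each nucleus sharp in its assigned layer only.

    Defocus is modelled as a Gaussian blur of the nucleus patch with
    sigma = defocus_sigma_per_layer * |layer - sharp_layer|.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _make_truth(spec, rng)
    patches = [_render_nucleus(spec, t, rng) for t in truth.nuclei]
    planes = []
    for layer in range(spec.n_layers):
        img = _scene_base(spec, truth)
        for t, (patch, pr) in zip(truth.nuclei, patches):
            dz = abs(layer - t.sharp_layer)
            if dz == 0:
                blurred = patch
            else:
                blurred = ndimage.gaussian_filter(
                    patch, sigma=spec.defocus_sigma_per_layer * dz
                )
            _composite(img, blurred, t.row, t.col, pr)
        img = _apply_noise(img, spec, rng)
        planes.append(
            ImagePlane(pixels=img, channel_label="dapi",
                       source_path=f"synthetic[z={layer}]")
        )
    return ZStack(planes=tuple(planes), z_step=0.3), truth


def gen_tunel_pair(
    spec: SceneSpec, shift: tuple[int, int] = (0, 0)
) -> tuple[ImagePlane, ImagePlane, GroundTruth]:
    """Render a registered DAPI/GFP pair sharing one field.

    The DAPI plane carries every nucleus; the GFP plane carries only the
    TUNEL-positive subset and is translated by the planted integer ``shift``
    (wrap-around), then receives independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _make_truth(spec, rng)
    truth.shift = (int(shift[0]), int(shift[1]))
    dapi = _scene_base(spec, truth)
    gfp = np.full(spec.shape, spec.background)
    for t in truth.nuclei:
        patch, pr = _render_nucleus(spec, t, rng)
        _composite(dapi, patch, t.row, t.col, pr)
        if t.tunel_positive:
            # TUNEL signal: same nucleus footprint, bright in the GFP channel
            gpatch = np.zeros_like(patch)
            rr, cc = draw_disk((pr, pr), t.radius, shape=gpatch.shape)
            gpatch[rr, cc] = spec.condensed_intensity
            _composite(gfp, gpatch, t.row, t.col, pr)
    gfp = np.roll(gfp, truth.shift, axis=(0, 1))
    dapi = _apply_noise(dapi, spec, rng)
    gfp = _apply_noise(gfp, spec, rng)
    return (
        ImagePlane(pixels=dapi, channel_label="dapi", source_path="synthetic-dapi"),
        ImagePlane(pixels=gfp, channel_label="gfp", source_path="synthetic-gfp"),
        truth,
    )
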