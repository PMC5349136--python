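# Methods

This note documents the models and procedures behind `nucleoscan`, the
parameters that matter, the numerical choices, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Detection: two-stage Circle Hough Transform

Stained nuclei are close enough to circles that circle detection doubles as
segmentation. Detection runs in two stages.

**Stage 1 — vote accumulation.** Sobel gradients are computed per plane; a
pixel is an edge when its gradient magnitude is at least
`edge_gradient_threshold` (default 0.20) times the maximum magnitude of the
plane. Each edge pixel casts one vote per candidate radius r ∈
[`radius_min`, `radius_max`] (defaults 4–13 px, matching nuclei imaged at
400–1000×) at distance r along both polarities of its unit gradient, into a
(radius, row, col) accumulator. The accumulator is smoothed per radius slice
with a σ = 1 px Gaussian, and 3-D local maxima above a small internal floor
(8% of the ideal smoothed peak r/σ², the response 2πr coincident votes would
produce under the same smoothing) become *candidates*. Rounding votes to the
nearest pixel rather than bilinear splatting is deliberate: the candidate
stage only needs to propose approximate centers.

**Stage 2 — perimeter support.** Accumulator peak height alone cannot
separate true circles from two systematic artifacts of this image class:
the *nucleolus ghost* (the nucleolus is itself a genuine small bright circle
inside a relaxed nucleus) and *satellite rings* (the boundary of a large
circle, voting at a smaller radius, lands its votes on a ring around the
true center, whose local maxima can out-score a true peak at small radii
after radius normalization). Each candidate is therefore re-scored by
perimeter support: an edge pixel supports the candidate when it lies at
distance r ± 1 px from the center and its gradient is radially aligned
(|cos θ| ≥ 0.9, i.e. within ≈26°; either polarity). Support is summarized
two ways:

* **coverage** — the fraction of ~2 px angular bins around the circle
  (max(8, round(πr)) bins) holding at least one supporter. A clean full
  circle scores ≈ 1 at any radius; a stray arc a fraction. Acceptance
  requires coverage ≥ `sensitivity` (default 0.70).
* **sharpness** — the gradient-magnitude-weighted mass of the supporters.
  Defocus both spreads an edge beyond the ±1 px ring and weakens its
  gradient, so the in-focus instance of a nucleus maximizes this score.
  (Raw supporter *counts* are not monotone in focus: mild defocus widens
  the edge band and can increase the count, which is why the weighting is
  essential.)

**Suppression.** Candidates conflict when their centers are closer than
`min_center_separation` (default `radius_min`: two nuclei can abut, but
their centers cannot be closer than one minimal radius) or when one center
lies inside the other's circle. Conflicts are resolved with a deterministic
priority: accepted candidates (coverage ≥ sensitivity) beat rejected ones,
larger radii beat smaller within them, then coverage, then (row, col,
radius). Preferring the containing circle is what absorbs nucleolus ghosts
and satellite rings into their parent nucleus. Ties are fully ordered, so
outputs are reproducible.

One parameter set is intended to serve a whole experiment acquired at fixed
magnification; all defaults are persistable through the batch YAML config.

## Z-stacks: counting each nucleus once

Detections are computed per layer, then grouped: two detections in
*adjacent* layers belong together when their centers are within
`link_distance` (default `radius_min`; centers drift little between 0.3 µm
sections). Groups are the transitive closure of adjacent-layer links, so a
nucleus visible in three or more sections forms one group; strict adjacency
means detections in layers 0 and 2 with nothing in layer 1 stay separate.
If transitivity would put two same-layer detections in one group, the
weaker is split out — one nucleus yields at most one detection per layer.
Each group contributes exactly one count, at its sharpest member (ties go
to the lower layer).

Within a stack the edge threshold is normalized by the *stack-wide* maximum
gradient rather than per plane. A plane whose nuclei are all defocused has
a weak maximum of its own, and per-plane normalization would promote blur
and noise to edge status there, creating spurious detections in layers far
from any focal plane (and with them, adjacency gaps and double counts).
Sharing the scale reflects that the planes of one acquisition share an
intensity scale. The same reasoning applies to the two channels of a TUNEL
pair (a TUNEL-negative GFP channel is nearly blank).

No auxiliary focus metric (Laplacian variance etc.) is used: the sharpness
score from the detector is the focus measure.

## Condensation scoring

Pixels inside each accepted circle are clustered into k = 4 intensity
clusters. The clustering is **exact 1-D k-means**: the optimal partition of
scalars is contiguous in sorted order, so dynamic programming over split
points (prefix-sum segment costs, O(k n²)) finds the global
minimum-within-cluster-SSE partition deterministically. This replaces
restarted Lloyd iterations entirely — there is no initialization, no seed
dependence, and no local-optimum risk; the `seed` argument of the API is
retained for interface stability but unused. When a circle holds fewer than
k distinct intensities, k degrades to that number and the decomposition
records it.

The branch rule uses a = brightest-cluster area fraction and d = the
brightness difference between brightest and darkest centroids. d is
*relative* by default, (c_max − c_min)/c_max, so the thresholds are
invariant to exposure scaling; an absolute-difference mode is available
behind `relative_difference=False`. Boundary semantics follow the rule's
wording literally: the nucleolus branch needs a < 0.15 (strict) and
d ≥ 0.20 (inclusive); the condensed-candidate branch needs a > 0.15 and
d > 0.30 (both strict); a = 0.15 exactly therefore falls to whole-circle
scoring. The three thresholds are configurable parameters with these
defaults. "Removing" the nucleolus means excluding its pixels from the
scored set (not subtracting its mean), which also shrinks the effective
radius slightly — by design, since the remaining area is what carries the
chromatin signal.

Classification uses three user-calibrated, pairwise-disjoint rectangles in
(effective radius, intensity) space. A point inside a rectangle takes its
label; a point in none takes the nearest rectangle's label, with distances
measured after scaling each axis by the overall calibration span, and exact
ties broken by the fixed order apoptotic > intermediate > non-apoptotic.
The shipped default calibration is derived from the synthetic generator's
parameter midpoints (condensed: intensity ≥ 0.72 at small effective radius;
relaxed: intensity ≤ 0.53 at large radius; an intermediate band between).
For real data, export the per-nucleus scatter
(`nucleoscan condensation --scatter`), plot intensity against effective
radius, and draw the three rectangles around the visible clusters; the
calibration is part of the YAML config.

A sample below 200 nuclei triggers a warning (not an error): ratio
estimates on smaller samples are statistically flimsy, but nothing in the
algorithms requires the floor.

## TUNEL

Registration is integer-pixel translation only: the shift maximizing the
normalized cross-correlation of the mean-subtracted planes, computed by FFT
(circular correlation) and searched within ±`max_shift` (default 16 px).
Subpixel refinement is omitted because detections are pixel-resolution
anyway. A correlation peak below 0.1 means the channels share too little
structure (e.g. a TUNEL-negative field); registration is declared failed
and shift (0, 0) is used, with a warning.

Matching is greedy nearest-neighbor in ascending distance, one-to-one: a
GFP detection is verified iff an unclaimed DAPI detection lies within
`match_distance` (default `radius_min`). Unverified GFP detections are
counted as rejected false detections. The readout is
100 × verified / n_DAPI.

## Synthetic scenes

The generator emulates what the analyses rely on: disk-like nuclei of 6–10
px radius inside a hyphal band (background 0.03, band 0.10), with two
morphologies — *relaxed* (body intensity 0.45, a nucleolus sub-disk of 8%
of the area at twice the body intensity, offset from center) and
*condensed* (a bright core at 0.90 covering 40% of the circle area on a
0.20 halo) — Poisson shot noise at 1500 photons per unit intensity plus
Gaussian read noise (σ = 0.01), defocus as Gaussian blur growing 2.0 px σ
per layer of distance from each nucleus's assigned in-focus layer, and
DAPI/GFP pairs related by a planted integer translation applied with
wrap-around (so shift recovery is exactly decidable). Placement uses a
jittered grid with spacing 2·r_max + 3, which guarantees the non-overlap
the ground-truth matching relies on. Everything is deterministic given the
seed.

What it does **not** emulate — and what passing tests therefore do not
demonstrate about real micrographs: overlapping or fused nuclei,
non-circular and fragmented nuclei (the intermediate apoptotic morphology
is not rendered; the intermediate calibration band is exercised only
geometrically), optics-accurate point-spread functions, uneven
illumination, autofluorescence gradients, hyphal branching, and
magnification variation. Real data additionally needs user calibration of
the state regions and possibly of the radius range.

## Numerical and interface choices

* Coordinates are 0-based (row, col); centers are reported at pixel
  resolution.
* Images are normalized to [0, 1] by the bit-depth maximum (8/16-bit TIFF
  and PNG supported; a constant image stays constant; writers round-trip
  within one quantization step). RGB inputs yield exactly the requested
  channel, never a luminance mix.
* Hyphal contour ROI: Otsu (or fixed) threshold, morphological closing
  with a 2 px disk, removal of components below `min_object_px`; an empty
  result degrades to the full frame with a warning. Detection is gated by
  the ROI: circles whose centers fall outside are discarded. ROIs can also
  be supplied as JSON polygons.
* All result orderings (detections, groups, batch rows) are fully
  deterministic; batch outputs are byte-identical under rerun with the
  same config and seed, and every result row carries a config fingerprint.
* Statistical comparison across strains/treatments (ANOVA etc.) is out of
  scope: the summary CSV (mean ± SEM per run) is designed to feed standard
  stats tools.

## Problem sizes in tests and the acceptance script

Recovery rates are measured on 50 fields (1–30 nuclei each), 50 six-layer
stacks (7–20 nuclei), 20 small oracle images (≤ 3 circles, 64×64), 100
tiny clustering cases, 20 fields across five condensed fractions, and 20
TUNEL pairs with shifts up to ±10 px — sizes at which the exhaustive
oracles remain exact and a full run stays in the tens of seconds on one
core.

## Known limitations

* Fused or heavily overlapping nuclei are merged by the containment rule —
  the count is conservative there (no watershed splitting, by design).
* The intermediate state is classified but not biologically validated by
  the synthetic scenes.
* Registration is translation-only; rotation or scale mismatch between
  channels is out of scope.
* Septum detection is not automated: hyphal segments are user ROIs.
* Very small nuclei (radius < 4 px) sit below the default radius range and
  would require rescaled parameters and a correspondingly harder
  ghost-suppression regime.
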