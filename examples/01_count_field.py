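"""Count nuclei in a single fluorescence field.

Renders a synthetic hyphal field with a known number of stained nuclei,
runs the Circle-Hough detector, and compares the count with the ground
truth. On real data you would load a micrograph with
``nucleoscan.read_image`` instead of generating one.
"""

from nucleoscan import DetectionParams, hough_circles
from nucleoscan.synth import SceneSpec, gen_field

plane, truth = gen_field(SceneSpec(n_nuclei=18, seed=11))
detections = hough_circles(plane, DetectionParams())

print(f"planted nuclei : {truth.n}")
print(f"detected nuclei: {len(detections)}")
print("first three detections (row, col, radius_px, sharpness):")
for d in detections[:3]:
    print(f"  ({d.row}, {d.col})  r={d.radius}  sharpness={d.sharpness:.0f}")

# Each detection is one nucleus; sharpness is the gradient-weighted mass of
# edge pointers to the circle center and ranks how crisply it is in focus.
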