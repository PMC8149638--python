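"""Percent-area load quantification on a synthetic stain image.

Builds a grayscale image with bright blobs on a noisy background,
segments it with a strict intensity threshold, and measures (a) the
overall load -- percent of the region's area above threshold -- and
(b) local loads inside 100 µm-diameter discs centered on three
plaque-like objects, the per-object variant used around amyloid
deposits.
"""

import numpy as np
from scipy import ndimage

from plaqueprox import build_roi, disc_loads, load_percentage, threshold_mask

rng = np.random.default_rng(0)
shape = (256, 256)
centers = [(64, 64), (128, 180), (200, 90)]

image = rng.normal(10.0, 2.0, shape)  # background
for r, c in centers:  # bright stained blobs, sigma 8 px
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    image += 60.0 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 8.0**2))

region = build_roi(np.ones(shape, bool), pixel_size=1.0, sample_id="cortex")
mask = threshold_mask(image, 25.0)

overall = load_percentage(mask, region)
print(f"overall load: {overall.load:.2f}% of {overall.region_area} px "
      f"({overall.positive_area} px above threshold)")

for m in disc_loads(mask, centers, pixel_size=1.0, diameter_um=100.0):
    print(f"  {m.region_id}: {m.load:.1f}% of a {m.region_area}-px disc positive")
print("-> the overall load stays in the few-percent range while the "
      "100 µm discs centered on the objects are heavily stained.")
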