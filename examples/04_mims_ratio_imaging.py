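"""MIMS quantification: ratio image, HSI render, ROI statistics, nuclei.

Simulates a NanoSIMS field with labeled regions at 0-300% above the 0.37%
natural 15N/14N baseline plus phosphorus-bright nuclei, then quantifies it:
per-pixel ratio image with a low-count validity mask, per-region mean percent
above background with standard errors, Otsu segmentation of nuclei from the
31P channel, and an HSI rendering written to disk.
"""

import numpy as np

from isopulse import RoiSet, hsi_render, ratio_image, roi_stats, segment_nuclei
from isopulse.mims_imaging import save_hsi_png
from isopulse.synthetic_data import RegionSpec, synthesize_mims_fields

regions = [
    RegionSpec(1, 0.0, ("rect", 10, 10, 50, 50), class_tag="stroma"),
    RegionSpec(2, 150.0, ("rect", 10, 60, 50, 100), class_tag="granulosa"),
    RegionSpec(3, 300.0, ("rect", 60, 10, 100, 50), class_tag="OSE"),
    RegionSpec(4, 50.0, ("disk", 80, 80, 12), class_tag="oocyte", is_nucleus=True),
]
stack = synthesize_mims_fields((110, 110), regions, mean_14n_counts=10_000, seed=9)

img = ratio_image(stack)  # 0.37% baseline, pixels with <20 counts masked
rois = RoiSet(stack.labels, {r.label: r.class_tag for r in regions})
table = roi_stats(img, rois)
print(table[["label", "class_tag", "n_pixels", "mean_percent_above",
             "se_percent_above"]].round(2).to_string(index=False))
print(
    "\nEach region's mean percent-above-background recovers its generating\n"
    "level (0/150/300/50%) within a few standard errors of Poisson counting."
)

nuclei = segment_nuclei(stack.p31)
print(f"\nnuclei found from the 31P channel: {nuclei.max()}")

render = hsi_render(img, 0.0, 300.0)
save_hsi_png(render, "mims_hsi.png")
print("HSI render (blue = 0%, magenta = 300% above background): mims_hsi.png")
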