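"""Ratiometric dipole-potential imaging on one synthetic image pair.

Builds a 512x512 two-excitation-channel image of ~35 ring-stained cells with
a known membrane excitation ratio, then runs the full pipeline: seeded
watershed segmentation, membrane-band extraction, background estimation and
pixelwise background-subtracted ratioing.  The mean membrane ratio tracks the
membrane dipole potential.
"""

import numpy as np

from tevcf.imaging import analyze_ratio_image, ratio_histogram
from tevcf.synthetic import simulate_ratio_images

image = simulate_ratio_images(
    ratio_true=0.620, n_cells=35, background_level=50.0, noise_sd=3.0, rng=101
)
seg, result = analyze_ratio_image(image, band_width_px=3)

print(f"cells segmented:      {seg.labels.max()} (one label per seed)")
print(f"background estimate:  blue {seg.background_blue:.1f}, red {seg.background_red:.1f} "
      f"(truth {image.truth.background_level})")
print(f"membrane pixels used: {result.n_membrane_pixels} ({result.n_excluded} excluded)")
print(f"mean excitation ratio: {result.mean_ratio:.4f} (generator truth 0.6200)")

counts, edges = ratio_histogram(result, np.arange(0.50, 0.75, 0.01))
mode = edges[np.argmax(counts)] + 0.005
print(f"pixelwise histogram mode: {mode:.3f}")
print("A lower ratio would indicate a reduced dipole potential at the")
print("membrane-water interface; a higher ratio, an elevated one.")
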