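"""Generate a small suite of synthetic knee-ultrasound phantoms.

Each phantom carries its exact generating geometry (bone curve, cartilage
mask, thickness), which is what makes every later stage testable.
"""

import numpy as np

from kneeus import PhantomSpec, generate_phantom, phantom_suite

# one phantom with the default appearance (speckle, interface echo,
# soft-tissue layers, mild lateral misalignment)
image, truth = generate_phantom(PhantomSpec(rng_seed=7))
print(f"image: {image.shape[0]} rows x {image.shape[1]} cols "
      f"at {image.spacing_mm} mm/px")
print(f"bone apex depth: {truth.bone_rows.max() * image.spacing_mm:.1f} mm, "
      f"cartilage thickness: {truth.thickness_mm:.2f} mm, "
      f"mask pixels: {truth.cartilage_mask.sum()}")

# a reproducible suite with thickness drawn from the healthy range
suite = phantom_suite(5, rng_seed=7)
thicknesses = [t.thickness_mm for _, t in suite]
print(f"suite thicknesses (mm): {np.round(thicknesses, 2)}")
# Thickness values sample the 1.69-2.55 mm healthy femoral range; the mask
# band height is thickness / 0.15 mm rounded to whole pixels.
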