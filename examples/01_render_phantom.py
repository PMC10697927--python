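"""Render the synthetic dynamic heart phantom and inspect its ground truth.

Builds the default mouse-thorax phantom (RV/LV/MYO compartments, 60-minute
variable framing, 1.2 mm PSF, frame-dependent noise) and prints the peak
time and peak activity of each compartment's true time-activity curve.
"""

import numpy as np

from nmfidif import default_phantom_spec, render_dynamic_image

spec = default_phantom_spec(seed=0)
image, truth = render_dynamic_image(spec)

print(f"image shape {image.data.shape}, voxel size {image.voxel_size_mm} mm")
print(f"{image.n_frames} frames covering {image.framing[-1].sum():.0f} s\n")
print(f"{'region':>6} {'voxels':>7} {'peak kBq/mL':>12} {'peak time s':>12}")
for name, tac in truth.region_tacs.items():
    n_vox = truth.region_masks[name].sum()
    k = np.argmax(tac.values)
    print(f"{name:>6} {n_vox:>7d} {tac.values[k]:>12.2f} {tac.times_s[k]:>12.0f}")

# The right ventricle peaks first, the left ventricle a few seconds later,
# and the myocardium last with sustained late retention - the kinetic
# ordering the component classifier relies on.
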