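"""NMF-unmixed left-ventricle input function.

Runs the full unmixing chain (PCA -> whitening -> non-negative ICA -> NMF)
on the heart-VOI voxel matrix of the noisy phantom, labels the components
by their kinetics, and compares the LV voxel-average TAC with truth.
"""

import warnings

import numpy as np

from nmfidif import SphericalVoi, default_phantom_spec, render_dynamic_image
from nmfidif.components import extract_nmf_idif
from nmfidif.io import voi_mask
from nmfidif.phantom import HEART_CENTER_MM
from nmfidif.unmix import build_voxel_matrix

warnings.simplefilter("ignore")

image, truth = render_dynamic_image(default_phantom_spec(seed=0))
voi = SphericalVoi(HEART_CENTER_MM, 3.5)
Z = build_voxel_matrix(image, voi_mask(image, voi))
print(f"VOI voxel matrix: {Z.n_frames} frames x {Z.n_voxels} voxels")

lv_tac, components = extract_nmf_idif(Z, n_components=3, seed=0)
print(f"labels: {components.labels}")
print(f"peak times (s): {np.round(components.peak_times_s, 0)}")
for i, label in enumerate(components.labels):
    print(f"  component {i} ({label}): {len(components.selected_voxels[i])} voxels with r > 0.9")

ref = truth.region_tacs["LV"]
r = np.corrcoef(lv_tac.values, ref.values)[0, 1]
t_min = ref.times_s / 60.0
print(f"\nNMF-IDIF vs true LV: Pearson r = {r:.4f}")
print(f"integral 0-60 min: NMF-IDIF {np.trapezoid(lv_tac.values, t_min):.1f}  "
      f"true {np.trapezoid(ref.values, t_min):.1f} kBq/mL*min")

# The LV component's high-probability voxels sit in the blood-pool core,
# so their average tracks the true blood curve closely even under PSF
# mixing and noise.
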