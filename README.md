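# nmfidif

Non-invasive kinetic modeling of dynamic small-animal PET needs the tracer
concentration in arterial plasma — the *input function*. Drawing it from the
image (an image-derived input function, IDIF) avoids blood sampling, but in a
mouse the left-ventricle blood pool is only a few mm³, so partial-volume
mixing with the right ventricle, the myocardium and sometimes the liver
biases any simple delineation. `nmfidif` implements a source-separation
route: non-negative matrix factorization of the heart-VOI voxel TACs,
initialized with non-negative ICA, unmixes those tissue signals and extracts
an unbiased left-ventricle blood curve (the *NMF-IDIF*), which then feeds
metabolite correction and two-tissue-compartment (2TCM) modeling.

The package is aimed at preclinical PET researchers who quantify brain (or
other organ) kinetics from heart-derived input functions, and at anyone who
wants a fully synthetic, ground-truth-controlled testbed for input-function
extraction methods.

## Method

Let `Z` (frames × voxels) hold the TACs of all voxels in a 3.5 mm spherical
heart VOI. The unmixing chain is

1. **PCA reduction** — `x = Bᵀ Z`, with `B` the `n` leading eigenvectors of
   the covariance of `Z`;
2. **symmetric whitening** — `z = E D^{-1/2} Eᵀ x = M x`, from the
   eigendecomposition of cov(`x`);
3. **non-negative ICA** — geodesic rotation descent on the orthogonal group
   minimizing `J(W) = mean(min(Wz, 0)²)`, giving sources `y = Wz` and the
   mixing matrix `A = B M⁻¹ Wᵀ` in frame space;
4. **NMF refinement** — multiplicative Frobenius updates started from
   `G₀ = |A|`, `H₀ = |y|`, yielding `Z ≈ G H` with component TACs in `G` and
   voxel weights in `H`.

Voxels are assigned by relative probability `r_ij = h_ij / Σ_i h_ij`; voxels
with `r > 0.9` define each component's region, and region TACs are plain
voxel averages (preserving activity scale). Components are labeled by
kinetics — RV peaks before LV, MYO after, and the liver shows slow uptake —
and the component count is chosen automatically by a correlation-redundancy
rule (threshold 0.7) over `n = 2…4`.

Downstream, the whole-blood LV curve is converted to metabolite-corrected
plasma via a linear plasma/whole-blood ratio fit and a decreasing-sigmoid
parent-fraction fit, and regional TACs are fitted with the reversible 2TCM
(`K1, k2, k3, k4`), reporting `V_T = K1/k2 (1 + k3/k4)` and the
frame-duration-weighted symmetric mean absolute percentage error

    wsMAPE = Σ_f T_f |TAC_f − C_f| / [ Σ_f T_f |TAC_f + C_f| / 2 ].

Everything is validated against a synthetic dynamic heart phantom
(`nmfidif.phantom`) with known compartment TACs, Gaussian PSF spill-over and
frame-duration-dependent noise.

## Worked example

```python
import numpy as np
from nmfidif import SphericalVoi, default_phantom_spec, render_dynamic_image
from nmfidif.components import extract_nmf_idif
from nmfidif.io import voi_mask
from nmfidif.phantom import HEART_CENTER_MM
from nmfidif.unmix import build_voxel_matrix

image, truth = render_dynamic_image(default_phantom_spec(seed=0))
Z = build_voxel_matrix(image, voi_mask(image, SphericalVoi(HEART_CENTER_MM, 3.5)))
lv_tac, components = extract_nmf_idif(Z, n_components=3, seed=0)
print(components.labels)
print(np.corrcoef(lv_tac.values, truth.region_tacs["LV"].values)[0, 1])
```

prints

```
['RV', 'MYO', 'LV']
0.9961
```

i.e. the three heart tissues are found and labeled, and the extracted LV
curve correlates at r = 0.996 with the true blood curve despite PSF mixing
and noise. The threshold baseline on the same phantom
(`nmfidif.threshold.extract_threshold_idif`) gives a 0–60 min activity
integral of 134 kBq/mL·min against a true 20.4 (spill-in dominated), while
the NMF-IDIF integral is 21.9 — see `examples/06_full_comparison.py`, which
also shows the downstream effect: fitted V_T with the threshold input
collapses, while the NMF-IDIF input keeps it near truth.

The `examples/` directory holds one short narrative script per capability
(phantom rendering, both IDIF extractions, blood correction, 2TCM fitting,
full comparison); each prints the numbers it computes and what they mean.
A thin CLI (`nmfidif phantom | idif | nmf-idif | blood-correct | fit-2tcm |
compare | run-all`) wraps the same functions for shell use on NIfTI images
with frame-timing CSV sidecars.

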