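"""Shared fixtures: phantoms and voxel matrices reused across test modules."""

import numpy as np
import pytest

from nmfidif import SphericalVoi, default_phantom_spec, render_dynamic_image
from nmfidif.io import voi_mask
from nmfidif.phantom import HEART_CENTER_MM
from nmfidif.unmix import build_voxel_matrix


@pytest.fixture(scope="session")
def heart_voi():
    return SphericalVoi(HEART_CENTER_MM, 3.5)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, PSF-free three-region phantom: exactly separable."""
    spec = default_phantom_spec(psf_fwhm_mm=0.0, noise_scale=0.0)
    return render_dynamic_image(spec)


@pytest.fixture(scope="session")
def clean_Z(clean_phantom, heart_voi):
    image, _ = clean_phantom
    return build_voxel_matrix(image, voi_mask(image, heart_voi))


@pytest.fixture(scope="session")
def mixed_phantom():
    """Default realistic phantom: PSF blur plus frame-dependent noise."""
    spec = default_phantom_spec(seed=0)
    return render_dynamic_image(spec)


@pytest.fixture(scope="session")
def voxel_region_labels(clean_phantom, clean_Z):
    """True region label of every voxel column of the clean VOI matrix."""
    _, truth = clean_phantom
    labels = np.empty(clean_Z.n_voxels, dtype=object)
    labels[:] = ""
    for name, mask in truth.region_masks.items():
        labels[mask[tuple(clean_Z.voxel_indices.T)]] = name
    return labels
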