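"""Baseline image-derived input function by activity thresholding.

The classical recipe: draw a spherical VOI over the heart, find the frame
with the highest VOI activity, keep the voxels whose activity in that frame
reaches a fraction (default 50%) of the VOI maximum, and average their TACs.
Because the selection cannot distinguish blood pool from spilled-in
myocardial signal, the resulting curve inherits a late-phase positive bias —
the bias the NMF unmixing route is designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DynamicImage, SphericalVoi, Tac, voi_mask

__all__ = ["ThresholdIdifResult", "extract_threshold_idif"]


@dataclass
class ThresholdIdifResult:
    """Voxel selection and mean TAC from threshold delineation."""

    selected_voxels: np.ndarray  # boolean mask on the image grid
    reference_frame: int
    tac: Tac


def extract_threshold_idif(
    image: DynamicImage, voi: SphericalVoi, threshold_fraction: float = 0.5
) -> ThresholdIdifResult:
    """Extract the threshold-delineated IDIF from a heart VOI.

    The reference frame is the frame maximizing total VOI activity (ties
    broken toward the earlier frame).  Voxels whose value in that frame is
    at least ``threshold_fraction`` times the VOI maximum are averaged,
    unweighted, over all frames.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    mask = voi_mask(image, voi)
    voi_tacs = image.data[mask]  # (n_voxels, n_frames)
    ref_frame = int(np.argmax(voi_tacs.sum(axis=0)))
    ref_vals = voi_tacs[:, ref_frame]
    cutoff = threshold_fraction * ref_vals.max()
    keep = ref_vals >= cutoff
    selected = np.zeros(image.grid_shape, dtype=bool)
    selected[mask] = keep
    mean_tac = voi_tacs[keep].mean(axis=0)
    tac = Tac(image.frame_mid_times_s, image.frame_durations_s, mean_tac)
    return ThresholdIdifResult(selected_voxels=selected, reference_frame=ref_frame, tac=tac)
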