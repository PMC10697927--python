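"""Containers and I/O for dynamic PET images, time-activity curves and VOIs.

Conventions fixed here and shared by every other module:

* image axes are ``(x, y, z, frame)``; activity is in kBq/mL unless a curve
  has been SUV-scaled
* voxel indices are 0-based; the physical centre of voxel ``(i, j, k)`` is
  ``(i + 0.5) * voxel_size_mm`` from the grid corner, per axis
* frame timing travels in a CSV sidecar with columns
  ``frame_index,start_s,duration_s`` — never in the NIfTI header, which
  cannot portably encode variable frame durations
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DynamicImage",
    "Tac",
    "SphericalVoi",
    "frame_mid_times",
    "voi_mask",
    "suv_scale",
    "save_dynamic_image",
    "load_dynamic_image",
    "read_framing",
    "write_framing",
    "read_tac",
    "write_tac",
    "save_label_image",
]


def _as_framing(framing) -> np.ndarray:
    """Coerce a (start_s, duration_s) table to a validated float array."""
    arr = np.asarray(framing, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("framing must be an (n_frames, 2) table of (start_s, duration_s)")
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError("frame start times must be strictly increasing")
    if np.any(arr[:, 1] <= 0):
        raise ValueError("frame durations must be positive")
    if np.any(arr[1:, 0] < arr[:-1, 0] + arr[:-1, 1] - 1e-9):
        raise ValueError("frames must not overlap")
    return arr


def frame_mid_times(framing) -> np.ndarray:
    """Mid-time of each frame in seconds: start + duration / 2."""
    arr = _as_framing(framing)
    return arr[:, 0] + arr[:, 1] / 2.0


@dataclass
class DynamicImage:
    """A 4D dynamic PET volume with voxel spacing and frame timing.

    Parameters
    ----------
    data
        Activity array of shape ``(nx, ny, nz, n_frames)`` in kBq/mL.
        Values must be finite; small negative excursions are allowed
        because iteratively reconstructed images carry them as noise.
    voxel_size_mm
        Physical voxel edge lengths ``(sx, sy, sz)`` in millimetres.
    framing
        ``(n_frames, 2)`` table of ``(start_s, duration_s)``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    framing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D with axes (x, y, z, frame)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image activities must be finite")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive lengths")
        self.framing = _as_framing(self.framing)
        if self.framing.shape[0] != self.data.shape[3]:
            raise ValueError(
                f"framing has {self.framing.shape[0]} rows but image has "
                f"{self.data.shape[3]} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_mid_times_s(self) -> np.ndarray:
        return frame_mid_times(self.framing)

    @property
    def frame_durations_s(self) -> np.ndarray:
        return self.framing[:, 1].copy()

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical centre coordinates of every voxel."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.voxel_size_mm)
        )


@dataclass
class Tac:
    """A time-activity curve sampled at frame mid-times.

    ``times_s`` are frame mid-times, ``durations_s`` the frame lengths
    (carried along because duration-weighted error metrics need them),
    and ``values`` the activity in kBq/mL (or SUV after scaling).
    """

    times_s: np.ndarray
    durations_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times_s) == len(self.durations_s) == len(self.values)):
            raise ValueError("times, durations and values must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("TAC times must be strictly increasing")
        if np.any(self.durations_s <= 0):
            raise ValueError("frame durations must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "Tac":
        """Copy of this curve with the same timing and new values."""
        return Tac(self.times_s.copy(), self.durations_s.copy(), np.asarray(values, float))


@dataclass(frozen=True)
class SphericalVoi:
    """Spherical volume of interest in physical (mm) image coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must be a triple")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


def voi_mask(image: DynamicImage, voi: SphericalVoi) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within the sphere.

    A voxel belongs to the VOI iff the Euclidean distance from its physical
    centre to ``voi.center_mm`` is at most ``voi.radius_mm``.

    Raises
    ------
    ValueError
        If no voxel centre falls inside the sphere (e.g. the VOI lies
        outside the grid).
    """
    cx, cy, cz = image.voxel_centers_mm()
    dx = cx - voi.center_mm[0]
    dy = cy - voi.center_mm[1]
    dz = cz - voi.center_mm[2]
    d2 = (
        dx[:, None, None] ** 2
        + dy[None, :, None] ** 2
        + dz[None, None, :] ** 2
    )
    mask = d2 <= voi.radius_mm**2
    if not mask.any():
        raise ValueError("VOI contains no voxel centres; check center/radius against the grid")
    return mask


def suv_scale(tac: Tac, injected_dose_mbq: float, body_weight_g: float) -> Tac:
    """Scale an activity-concentration TAC (kBq/mL) to standardized uptake value.

    SUV = concentration / (injected dose / body weight), so with the dose
    converted to kBq the result carries units g/mL (dimensionless by the
    usual 1 g/mL tissue-density convention).
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_g <= 0:
        raise ValueError("body weight must be positive")
    dose_kbq = injected_dose_mbq * 1000.0
    return tac.with_values(tac.values / (dose_kbq / body_weight_g))


# ---------------------------------------------------------------------------
# File I/O


def _affine(voxel_size_mm) -> np.ndarray:
    sx, sy, sz = voxel_size_mm
    aff = np.diag([sx, sy, sz, 1.0])
    # translation places voxel (0,0,0) at its centre (0.5 * spacing)
    aff[:3, 3] = [sx / 2.0, sy / 2.0, sz / 2.0]
    return aff


def write_framing(framing, path) -> None:
    arr = _as_framing(framing)
    df = pd.DataFrame(
        {"frame_index": np.arange(len(arr)), "start_s": arr[:, 0], "duration_s": arr[:, 1]}
    )
    df.to_csv(path, index=False)


def read_framing(path) -> np.ndarray:
    df = pd.read_csv(path)
    df = df.sort_values("frame_index")
    return _as_framing(df[["start_s", "duration_s"]].to_numpy())


def save_dynamic_image(image: DynamicImage, nifti_path, framing_path) -> None:
    """Write the 4D volume as NIfTI-1 (float32) plus a frame-timing sidecar."""
    img = nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm))
    nib.save(img, str(nifti_path))
    write_framing(image.framing, framing_path)


def load_dynamic_image(nifti_path, framing_path) -> DynamicImage:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    framing = read_framing(framing_path)
    return DynamicImage(data, voxel_size, framing)


def write_tac(tac: Tac, path) -> None:
    pd.DataFrame(
        {"time_s": tac.times_s, "duration_s": tac.durations_s, "value": tac.values}
    ).to_csv(path, index=False)


def read_tac(path) -> Tac:
    df = pd.read_csv(path)
    return Tac(df["time_s"].to_numpy(), df["duration_s"].to_numpy(), df["value"].to_numpy())


def save_label_image(labels: np.ndarray, voxel_size_mm, path) -> None:
    """Write an integer label volume (e.g. region masks) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_size_mm))
    nib.save(img, str(path))
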