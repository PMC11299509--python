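"""Shared containers and constants for the lacuno-canalicular morphometry pipeline.

Conventions used across the package (stated once, used everywhere):

* 3D stacks are indexed ``(slice, row, col)`` = ``(z, y, x)`` with an
  isotropic voxel size in micrometres; slice index runs distal to proximal.
* 2D fields are indexed ``(row, col)`` with the origin at the top-left;
  the image vertical axis (rows) is the reference for canaliculus angles,
  measured in degrees, clockwise-positive, wrapped to ``(-90, 90]``.
* All physical quantities are carried in um / um^2 / um^3; unit conversion
  happens exactly once, at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Pore volume bands (um^3). A pore is noise below NOISE_MAX_UM3, an
# osteocyte lacuna in [NOISE_MAX_UM3, LACUNA_MAX_UM3) and an intracortical
# canal at or above LACUNA_MAX_UM3. Boundary ties go to the higher band.
NOISE_MAX_UM3 = 25.0
LACUNA_MAX_UM3 = 2000.0

CLASS_NOISE = "noise"
CLASS_LACUNA = "lacuna"
CLASS_CANAL = "canal"
PORE_CLASSES = (CLASS_NOISE, CLASS_LACUNA, CLASS_CANAL)


def classify_volume_um3(volume_um3: float) -> str:
    """Assign a pore class from its volume in um^3 (ties resolved upward)."""
    if volume_um3 < NOISE_MAX_UM3:
        return CLASS_NOISE
    if volume_um3 < LACUNA_MAX_UM3:
        return CLASS_LACUNA
    return CLASS_CANAL


@dataclass
class VoxelVolume:
    """A 3D grayscale stack with an isotropic voxel size.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; any scalar dtype.
    voxel_size_um
        Isotropic voxel edge length in micrometres (0.65 for the
        synchrotron scans this pipeline targets).
    """

    data: np.ndarray
    voxel_size_um: float = 0.65

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("VoxelVolume.data must be a nonempty 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3


@dataclass
class Field2D:
    """A 2D histology field (grayscale or RGB) with pixel size and bone ROI."""

    image: np.ndarray
    pixel_size_um: float
    bone_roi: np.ndarray | None = None  # boolean mask; None = whole field

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim not in (2, 3) or self.image.size == 0:
            raise ValueError("Field2D.image must be a nonempty 2D or RGB array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bone_roi is not None:
            self.bone_roi = np.asarray(self.bone_roi, dtype=bool)
            if self.bone_roi.shape != self.image.shape[:2]:
                raise ValueError("bone_roi shape must match image")
            if not self.bone_roi.any():
                raise ValueError("bone_roi is empty")

    def grayscale(self) -> np.ndarray:
        """Image as float grayscale (luminance average over RGB channels)."""
        img = self.image
        if img.ndim == 3:
            img = img[..., :3].mean(axis=-1)
        return img.astype(np.float64)

    def roi_mask(self) -> np.ndarray:
        if self.bone_roi is not None:
            return self.bone_roi
        return np.ones(self.image.shape[:2], dtype=bool)


@dataclass
class RoiSlab:
    """Axial region-of-interest: a slab of fixed physical extent placed at a
    fixed physical offset distal of a reference slice."""

    reference_slice: int
    offset_um: float = 100.0
    extent_um: float = 500.0


@dataclass
class LacunarMetrics:
    """Per-sample lacunar summary over one analyzed cortical ROI."""

    n_lacunae: int
    cortical_bone_volume_mm3: float
    density_per_mm3: float
    proportion_pct: float
    mean_volume_um3: float  # NaN when no lacunae
    mean_sphericity: float  # NaN when no lacunae / no valid meshes

    def as_dict(self) -> dict[str, float]:
        return {
            "n_lacunae": self.n_lacunae,
            "cortical_bone_volume_mm3": self.cortical_bone_volume_mm3,
            "density_per_mm3": self.density_per_mm3,
            "proportion_pct": self.proportion_pct,
            "mean_volume_um3": self.mean_volume_um3,
            "mean_sphericity": self.mean_sphericity,
        }


@dataclass
class LcnFieldResult:
    """Per-field LCN quantification."""

    lcn_area_fraction_pct: float
    mean_canaliculus_length_um: float
    aligned_fraction: float
    n_canaliculi_traced: int = 0


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an axial angle (degrees) to the interval (-90, 90].

    Canaliculus orientations are axial (undirected), so angles are taken
    modulo 180 degrees.
    """
    wrapped = -((-np.asarray(angle, dtype=float) + 90.0) % 180.0 - 90.0)
    return wrapped if np.ndim(angle) else float(wrapped)
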