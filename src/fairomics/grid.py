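"""Geometry-aware volume and mask containers.

Index convention is 0-based ``(slice, row, col)``.  Patient coordinates are
LPS millimetres; a voxel center maps to patient space as

    x = origin + D @ (spacing * index)

where ``D`` is a 3x3 matrix whose *columns* are the unit direction cosines
of the slice, row and column axes, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridGeometry", "ImageVolume", "BinaryMask"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Origin, spacing and direction cosines of a regular 3-D grid."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    direction: np.ndarray  # 3x3, columns = (slice, row, col) axes

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", d)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if abs(abs(np.linalg.det(d)) - 1.0) > _ORTHO_TOL:
            raise ValueError("direction matrix is not orthonormal")

    def index_to_patient(self, index: np.ndarray) -> np.ndarray:
        """Map fractional (slice,row,col) indices to patient mm (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction.T

    def patient_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map patient-space mm points to fractional (slice,row,col) indices."""
        p = np.asarray(points, dtype=float) - np.asarray(self.origin)
        return (p @ self.direction) / np.asarray(self.spacing)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def congruent(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ImageVolume:
    """A 3-D scalar image with patient-space geometry.

    ``voxels`` is indexed (slice, row, col) and holds modality units
    (HU, SUV proxy, ADC) after rescale slope/intercept have been applied.
    """

    voxels: np.ndarray
    geometry: GridGeometry
    modality: str = "CT"
    patient_id: str = ""
    series_uid: str = ""
    frame_of_reference_uid: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slice,row,col)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def origin(self):
        return self.geometry.origin

    @property
    def spacing(self):
        return self.geometry.spacing

    @property
    def direction(self):
        return self.geometry.direction


@dataclass
class BinaryMask:
    """Boolean VOI mask congruent with an :class:`ImageVolume` grid."""

    bits: np.ndarray
    roi_name: str
    grid_ref: GridGeometry

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def voxel_count(self) -> int:
        return int(self.bits.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape
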