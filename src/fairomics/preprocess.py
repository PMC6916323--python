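"""Masked-intensity preparation: re-segmentation, resampling, discretization.

Gray-level discretization follows the fixed-bin-width rule

    level(x) = floor((x - min) / w) + 1

anchored at the region minimum, or the fixed-bin-count rule

    level(x) = min(n, floor(n * (x - min) / (max - min)) + 1).

Every preprocessing setting that can change a feature value is carried in
:class:`ExtractionConfig` and serialized into the provenance graph, so no
step is implicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import SimpleITK as sitk
import yaml

from .grid import BinaryMask, GridGeometry, ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "ExtractionConfig",
    "DiscretizedRegion",
    "resegment",
    "resample",
    "discretize_fbw",
    "discretize_fbc",
    "discretize",
]

ALL_FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings of one extraction run; hashed into a provenance fingerprint."""

    bin_width: float | None = 25.0
    bin_count: int | None = None
    resample_spacing: tuple[float, float, float] | None = None
    reseg_range: tuple[float, float] | None = None
    enabled_families: tuple[str, ...] = ALL_FAMILIES
    gldm_alpha: int = 0
    software_name: str = "fairomics"
    software_version: str = "0.1.0"
    software_language: str = "Python"

    def __post_init__(self) -> None:
        if (self.bin_width is None) == (self.bin_count is None):
            raise ValueError("exactly one of bin_width / bin_count must be set")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.bin_count is not None and self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        unknown = set(self.enabled_families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "ExtractionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("resample_spacing", "reseg_range", "enabled_families"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if "bin_count" in raw and raw["bin_count"] is not None:
            raw.setdefault("bin_width", None)
        return cls(**raw)


@dataclass
class DiscretizedRegion:
    """Masked voxels mapped to integer gray levels 1..Ng on the 3-D grid.

    ``level_grid`` keeps the levels in place (0 outside the mask) so texture
    neighborhoods can be evaluated; ``levels`` is the flat masked vector.
    """

    level_grid: np.ndarray  # int array, 0 outside mask
    mask: np.ndarray  # bool
    ng: int
    voxel_volume: float
    spacing: tuple[float, float, float]

    @property
    def levels(self) -> np.ndarray:
        return self.level_grid[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def histogram(self) -> np.ndarray:
        """Counts per level 1..Ng."""
        return np.bincount(self.levels, minlength=self.ng + 1)[1:]


def resegment(vol: ImageVolume, mask: BinaryMask, rng) -> BinaryMask:
    """Drop masked voxels whose intensity falls outside [lo, hi]."""
    lo, hi = rng
    keep = mask.bits & (vol.voxels >= lo) & (vol.voxels <= hi)
    if mask.voxel_count and not keep.any():
        log.warning("re-segmentation to [%s, %s] removed every voxel of %r", lo, hi, mask.roi_name)
    return BinaryMask(bits=keep, roi_name=mask.roi_name, grid_ref=mask.grid_ref)


def _to_sitk(arr: np.ndarray, geom: GridGeometry) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    img.SetOrigin(tuple(float(x) for x in geom.origin))
    img.SetSpacing((float(geom.spacing[2]), float(geom.spacing[1]), float(geom.spacing[0])))
    d = geom.direction
    img.SetDirection(tuple(np.column_stack([d[:, 2], d[:, 1], d[:, 0]]).ravel()))
    return img


def resample(vol: ImageVolume, mask: BinaryMask, new_spacing) -> tuple[ImageVolume, BinaryMask]:
    """Resample image (trilinear) and mask (nearest) onto a new grid.

    The new grid keeps the first-voxel-center at the old origin and spans
    the old physical extent.
    """
    new_spacing = tuple(float(s) for s in new_spacing)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new spacing must be positive")
    old = vol.geometry
    new_shape = tuple(
        int(np.floor((n - 1) * so / sn)) + 1
        for n, so, sn in zip(vol.shape, old.spacing, new_spacing)
    )
    if any(n < 1 for n in new_shape):
        raise ValueError("resampled grid would be empty")
    new_geom = GridGeometry(old.origin, new_spacing, old.direction)

    ref = sitk.Image((new_shape[2], new_shape[1], new_shape[0]), sitk.sitkFloat64)
    ref.SetOrigin(tuple(float(x) for x in new_geom.origin))
    ref.SetSpacing((new_spacing[2], new_spacing[1], new_spacing[0]))
    d = new_geom.direction
    ref.SetDirection(tuple(np.column_stack([d[:, 2], d[:, 1], d[:, 0]]).ravel()))

    img = sitk.Resample(_to_sitk(vol.voxels.astype(np.float64), old), ref, sitk.Transform(),
                        sitk.sitkLinear, 0.0)
    msk = sitk.Resample(_to_sitk(mask.bits.astype(np.uint8), old), ref, sitk.Transform(),
                        sitk.sitkNearestNeighbor, 0)
    new_vol = ImageVolume(
        voxels=sitk.GetArrayFromImage(img),
        geometry=new_geom,
        modality=vol.modality,
        patient_id=vol.patient_id,
        series_uid=vol.series_uid,
        frame_of_reference_uid=vol.frame_of_reference_uid,
    )
    new_mask = BinaryMask(
        bits=sitk.GetArrayFromImage(msk) > 0, roi_name=mask.roi_name, grid_ref=new_geom
    )
    return new_vol, new_mask


def _region_values(vol: ImageVolume, mask: BinaryMask) -> np.ndarray:
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if mask.voxel_count == 0:
        raise ValueError("cannot discretize an empty mask")
    return vol.voxels[mask.bits]


def discretize_fbw(vol: ImageVolume, mask: BinaryMask, width: float) -> DiscretizedRegion:
    """Fixed-bin-width discretization anchored at the region minimum."""
    if width <= 0:
        raise ValueError("bin width must be > 0")
    vals = _region_values(vol, mask)
    lo = vals.min()
    level_grid = np.zeros(vol.shape, dtype=np.int64)
    level_grid[mask.bits] = np.floor((vals - lo) / width).astype(np.int64) + 1
    ng = int(level_grid.max())
    return DiscretizedRegion(
        level_grid=level_grid,
        mask=mask.bits.copy(),
        ng=ng,
        voxel_volume=vol.geometry.voxel_volume,
        spacing=tuple(vol.geometry.spacing),
    )


def discretize_fbc(vol: ImageVolume, mask: BinaryMask, n_bins: int) -> DiscretizedRegion:
    """Fixed-bin-count discretization; a constant region maps to level 1."""
    if n_bins < 1:
        raise ValueError("bin count must be >= 1")
    vals = _region_values(vol, mask)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        lv = np.ones(vals.shape, dtype=np.int64)
    else:
        lv = np.minimum(n_bins, np.floor(n_bins * (vals - lo) / (hi - lo)).astype(np.int64) + 1)
    level_grid = np.zeros(vol.shape, dtype=np.int64)
    level_grid[mask.bits] = lv
    return DiscretizedRegion(
        level_grid=level_grid,
        mask=mask.bits.copy(),
        ng=int(level_grid.max()),
        voxel_volume=vol.geometry.voxel_volume,
        spacing=tuple(vol.geometry.spacing),
    )


def discretize(vol: ImageVolume, mask: BinaryMask, cfg: ExtractionConfig) -> DiscretizedRegion:
    if cfg.bin_width is not None:
        return discretize_fbw(vol, mask, cfg.bin_width)
    return discretize_fbc(vol, mask, cfg.bin_count)
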