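"""Synthetic DICOM phantom cases with analytically known geometry.

Every downstream stage (series reading, RTSTRUCT parsing, rasterization,
feature extraction) is tested against phantoms written by this module, so
all expected values are available in closed form: intensity patterns are
simple functions of the voxel index or the voxel-center patient coordinate,
and ROI contours are exact polygons.

Stored pixel values are 16-bit integers with RescaleSlope=1 and
RescaleIntercept=0, so read-back is exact rather than approximate.  All
UIDs are derived deterministically from the patient id, making repeated
writes reproducible.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grid import GridGeometry

__all__ = [
    "Constant",
    "AxisGradient",
    "UniformLevels",
    "SphereLesion",
    "RoiSpec",
    "PhantomSpec",
    "CaseHandle",
    "write_phantom_series",
    "write_phantom_rtstruct",
    "make_case",
    "random_roi_specs",
]

_SOP_CLASS = {
    "CT": "1.2.840.10008.5.1.4.1.1.2",
    "PT": "1.2.840.10008.5.1.4.1.1.128",
    "MR": "1.2.840.10008.5.1.4.1.1.4",
}
_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"


# ---------------------------------------------------------------------------
# intensity patterns


@dataclass(frozen=True)
class Constant:
    value: int = 0

    def evaluate(self, spec: "PhantomSpec") -> np.ndarray:
        return np.full(spec.grid_shape, self.value, dtype=np.int16)


@dataclass(frozen=True)
class AxisGradient:
    """Affine function of the voxel index: base + gk*k + gr*r + gc*c."""

    base: int = 0
    gains: tuple[int, int, int] = (1, 2, 3)

    def evaluate(self, spec: "PhantomSpec") -> np.ndarray:
        k, r, c = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
        gk, gr, gc = self.gains
        return (self.base + gk * k + gr * r + gc * c).astype(np.int16)


@dataclass(frozen=True)
class UniformLevels:
    """Cycle through ``n_levels`` values spaced ``step`` apart.

    When the voxel count is a multiple of ``n_levels`` every value occurs
    equally often, which makes histogram-based expectations exact.
    """

    n_levels: int = 8
    step: int = 25

    def evaluate(self, spec: "PhantomSpec") -> np.ndarray:
        n = int(np.prod(spec.grid_shape))
        flat = (np.arange(n) % self.n_levels) * self.step
        return flat.reshape(spec.grid_shape).astype(np.int16)


@dataclass(frozen=True)
class SphereLesion:
    """Foreground sphere on a constant background, classified at voxel centers."""

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_mm: float = 10.0
    fg: int = 100
    bg: int = -50

    def evaluate(self, spec: "PhantomSpec") -> np.ndarray:
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        geom = spec.geometry
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij"), axis=-1
        )
        centers = geom.index_to_patient(idx)
        inside = np.linalg.norm(centers - np.asarray(self.center_mm), axis=-1) <= self.radius_mm
        return np.where(inside, self.fg, self.bg).astype(np.int16)

    def inside_mask(self, spec: "PhantomSpec") -> np.ndarray:
        return self.evaluate(spec) == self.fg


# ---------------------------------------------------------------------------
# ROI specs

# In-plane shape coordinates are (u, v) millimetres measured from the grid
# origin: u runs along the column axis, v along the row axis.  This keeps
# shapes well-defined under non-identity orientations.


@dataclass(frozen=True)
class RoiSpec:
    name: str
    shape: str  # rectangle | circle | ring
    params: dict
    slice_range: tuple[int, int]  # inclusive [first, last]

    def polygons_uv(self) -> list[np.ndarray]:
        """Per-slice polygon set as (N,2) arrays of (u,v) mm."""
        if self.shape == "rectangle":
            u0, v0 = self.params["center_uv"]
            w, h = self.params["width"], self.params["height"]
            return [_rect(u0, v0, w, h)]
        if self.shape == "circle":
            u0, v0 = self.params["center_uv"]
            n = int(self.params.get("n_vertices", 64))
            if n < 3:
                raise ValueError("circle needs >= 3 vertices")
            return [_ngon(u0, v0, self.params["radius"], n)]
        if self.shape == "ring":
            u0, v0 = self.params["center_uv"]
            outer, inner = self.params["outer"], self.params["inner"]
            if inner >= outer:
                raise ValueError("ring inner extent must be strictly inside outer")
            kind = self.params.get("kind", "square")
            if kind == "square":
                return [_rect(u0, v0, 2 * outer, 2 * outer), _rect(u0, v0, 2 * inner, 2 * inner)]
            n = int(self.params.get("n_vertices", 64))
            return [_ngon(u0, v0, outer, n), _ngon(u0, v0, inner, n)]
        raise ValueError(f"unknown ROI shape {self.shape!r}")


def _rect(u0: float, v0: float, w: float, h: float) -> np.ndarray:
    du, dv = w / 2.0, h / 2.0
    return np.array(
        [[u0 - du, v0 - dv], [u0 + du, v0 - dv], [u0 + du, v0 + dv], [u0 - du, v0 + dv]]
    )


def _ngon(u0: float, v0: float, radius: float, n: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([u0 + radius * np.cos(ang), v0 + radius * np.sin(ang)])


# ---------------------------------------------------------------------------
# phantom spec


def _rotation_about_slice_axis(deg: float) -> np.ndarray:
    """Direction matrix for an axial stack, in-plane axes rotated by ``deg``.

    Columns are the (slice, row, col) axes in patient space: the slice
    axis is +z; at 0 degrees the column axis is +x and the row axis +y.
    """
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    slice_ax = [0.0, 0.0, 1.0]
    row_ax = [-s, c, 0.0]
    col_ax = [c, s, 0.0]
    return np.column_stack([slice_ax, row_ax, col_ax])


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (8, 16, 16)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_pattern: object = field(default_factory=Constant)
    rois: list[RoiSpec] = field(default_factory=list)
    patient_id: str = "PHANTOM-001"
    modality: str = "CT"
    rotation_deg: float = 0.0  # in-plane rotation; 0 = identity orientation
    seed: int = 20190101

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.modality not in _SOP_CLASS:
            raise ValueError(f"modality must be one of {sorted(_SOP_CLASS)}")
        if isinstance(self.intensity_pattern, SphereLesion):
            lo = self.geometry.index_to_patient(np.zeros(3))
            hi = self.geometry.index_to_patient(np.asarray(self.grid_shape) - 1.0)
            ctr = np.asarray(self.intensity_pattern.center_mm)
            r = self.intensity_pattern.radius_mm
            box_lo, box_hi = np.minimum(lo, hi), np.maximum(lo, hi)
            if np.any(ctr - r < box_lo) or np.any(ctr + r > box_hi):
                raise ValueError("sphere lesion must lie fully inside the grid")

    @property
    def geometry(self) -> GridGeometry:
        direction = _rotation_about_slice_axis(self.rotation_deg)
        return GridGeometry(tuple(self.origin), tuple(self.spacing), direction)

    def voxel_array(self) -> np.ndarray:
        return self.intensity_pattern.evaluate(self)

    # deterministic UIDs: repeated writes of the same spec are identical
    def _uid(self, *tags: str) -> str:
        return generate_uid(entropy_srcs=[self.patient_id, str(self.seed), *tags])


@dataclass(frozen=True)
class CaseHandle:
    series_dir: Path
    rtstruct_path: Path
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# writers


def write_phantom_series(spec: PhantomSpec, out_dir) -> list[Path]:
    """Write one DICOM Part-10 file per slice; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    voxels = spec.voxel_array()
    if voxels.min() < -(2**15) or voxels.max() >= 2**15:
        raise ValueError("phantom intensities must fit in int16")
    geom = spec.geometry
    d = geom.direction
    row_cos, col_cos = d[:, 1], d[:, 2]

    study_uid = spec._uid("study")
    series_uid = spec._uid("series")
    for_uid = spec._uid("frame")

    paths: list[Path] = []
    n_slices = spec.grid_shape[0]
    for k in range(n_slices):
        ds = Dataset()
        ds.file_meta = _file_meta(_SOP_CLASS[spec.modality], spec._uid("sop", str(k)))
        ds.SOPClassUID = _SOP_CLASS[spec.modality]
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.PatientID = spec.patient_id
        ds.PatientName = spec.patient_id
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = for_uid
        ds.Modality = spec.modality
        ds.StudyDate = ds.SeriesDate = "20190101"
        ds.StudyTime = ds.SeriesTime = "000000"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [*col_cos.tolist(), *row_cos.tolist()]
        pos = geom.index_to_patient(np.array([k, 0, 0], dtype=float))
        ds.ImagePositionPatient = [float(x) for x in pos]
        ds.PixelSpacing = [float(spec.spacing[1]), float(spec.spacing[2])]
        ds.SliceThickness = float(spec.spacing[0])
        ds.Rows, ds.Columns = spec.grid_shape[1], spec.grid_shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(voxels[k]).astype("<i2").tobytes()
        path = out_dir / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_phantom_rtstruct(spec: PhantomSpec, out_path, series_dir) -> Path:
    """Write the RTSTRUCT referencing an already-written series."""
    out_path = Path(out_path)
    series_dir = Path(series_dir)
    slice_files = sorted(series_dir.glob("*.dcm"))
    if not slice_files:
        raise FileNotFoundError(f"no series written under {series_dir}")
    refs = []
    for f in slice_files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        refs.append((int(ds.InstanceNumber) - 1, ds.SOPClassUID, ds.SOPInstanceUID))
    refs.sort()
    first = pydicom.dcmread(slice_files[0], stop_before_pixels=True)
    geom = spec.geometry

    rt = Dataset()
    rt.file_meta = _file_meta(_RTSTRUCT_SOP_CLASS, spec._uid("rtstruct"))
    rt.SOPClassUID = _RTSTRUCT_SOP_CLASS
    rt.SOPInstanceUID = rt.file_meta.MediaStorageSOPInstanceUID
    rt.PatientID = spec.patient_id
    rt.PatientName = spec.patient_id
    rt.StudyInstanceUID = first.StudyInstanceUID
    rt.SeriesInstanceUID = spec._uid("rtseries")
    rt.Modality = "RTSTRUCT"
    rt.StructureSetLabel = "phantom"
    rt.StructureSetDate = "20190101"
    rt.StructureSetTime = "000000"

    # frame-of-reference / series linkage
    contour_image = []
    for _, cls, uid in refs:
        item = Dataset()
        item.ReferencedSOPClassUID = cls
        item.ReferencedSOPInstanceUID = uid
        contour_image.append(item)
    rt_series = Dataset()
    rt_series.SeriesInstanceUID = first.SeriesInstanceUID
    rt_series.ContourImageSequence = contour_image
    rt_study = Dataset()
    rt_study.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
    rt_study.ReferencedSOPInstanceUID = first.StudyInstanceUID
    rt_study.RTReferencedSeriesSequence = [rt_series]
    frame_ref = Dataset()
    frame_ref.FrameOfReferenceUID = first.FrameOfReferenceUID
    frame_ref.RTReferencedStudySequence = [rt_study]
    rt.ReferencedFrameOfReferenceSequence = [frame_ref]

    struct_seq, contour_seq = [], []
    for i, roi in enumerate(spec.rois, start=1):
        s = Dataset()
        s.ROINumber = i
        s.ReferencedFrameOfReferenceUID = first.FrameOfReferenceUID
        s.ROIName = roi.name
        s.ROIGenerationAlgorithm = "MANUAL"
        struct_seq.append(s)

        c = Dataset()
        c.ReferencedROINumber = i
        c.ROIDisplayColor = [255, 0, 0]
        contours = []
        k_lo, k_hi = roi.slice_range
        for k in range(k_lo, k_hi + 1):
            if not 0 <= k < spec.grid_shape[0]:
                raise ValueError(f"ROI {roi.name!r} slice {k} outside grid")
            for poly in roi.polygons_uv():
                pts = _uv_to_patient(poly, k, geom)
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(poly)
                item.ContourData = [float(x) for x in pts.ravel()]
                ref = Dataset()
                ref.ReferencedSOPClassUID = refs[k][1]
                ref.ReferencedSOPInstanceUID = refs[k][2]
                item.ContourImageSequence = [ref]
                contours.append(item)
        c.ContourSequence = contours
        contour_seq.append(c)
    rt.StructureSetROISequence = struct_seq
    rt.ROIContourSequence = contour_seq

    rt.save_as(out_path, enforce_file_format=True)
    return out_path


def _uv_to_patient(poly_uv: np.ndarray, k: int, geom: GridGeometry) -> np.ndarray:
    """(u,v) in-plane mm on slice k -> (N,3) patient mm."""
    origin = np.asarray(geom.origin)
    d = geom.direction
    base = origin + d[:, 0] * (k * geom.spacing[0])
    return base + np.outer(poly_uv[:, 1], d[:, 1]) + np.outer(poly_uv[:, 0], d[:, 2])


def make_case(spec: PhantomSpec, out_dir) -> CaseHandle:
    """Write series + RTSTRUCT under ``out_dir`` (one case directory)."""
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    write_phantom_series(spec, series_dir)
    rt_path = write_phantom_rtstruct(spec, out_dir / "rtstruct.dcm", series_dir)
    return CaseHandle(series_dir=series_dir, rtstruct_path=rt_path, spec=spec)


# ---------------------------------------------------------------------------
# randomized ROI geometry for stress testing the rasterizers


def random_roi_specs(
    rng: np.random.Generator,
    n: int,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> list[RoiSpec]:
    """Random rectangles, 64-gon circles and rings staying inside the grid.

    Positions and sizes are drawn continuously, so polygon edges do not
    coincide with voxel-center rows/columns (no boundary-grazing ties).
    """
    n_k, n_r, n_c = grid_shape
    span_u = (n_c - 1) * spacing[2]
    span_v = (n_r - 1) * spacing[1]
    specs = []
    for i in range(n):
        kind = ("rectangle", "circle", "ring")[i % 3]
        u0 = rng.uniform(0.3 * span_u, 0.7 * span_u)
        v0 = rng.uniform(0.3 * span_v, 0.7 * span_v)
        max_half = 0.9 * min(u0, span_u - u0, v0, span_v - v0)
        k0 = int(rng.integers(0, n_k))
        k1 = int(rng.integers(k0, min(n_k, k0 + 4)))
        if kind == "rectangle":
            params = {
                "center_uv": (u0, v0),
                "width": rng.uniform(0.2, 2.0) * max_half,
                "height": rng.uniform(0.2, 2.0) * max_half,
            }
        elif kind == "circle":
            params = {
                "center_uv": (u0, v0),
                "radius": rng.uniform(0.2, 1.0) * max_half,
                "n_vertices": 64,
            }
        else:
            outer = rng.uniform(0.5, 1.0) * max_half
            params = {
                "center_uv": (u0, v0),
                "outer": outer,
                "inner": rng.uniform(0.2, 0.7) * outer,
                "kind": "square" if i % 2 else "circle",
                "n_vertices": 64,
            }
        specs.append(RoiSpec(name=f"roi_{i:03d}", shape=kind, params=params, slice_range=(k0, k1)))
    return specs
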