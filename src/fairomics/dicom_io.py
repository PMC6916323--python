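"""Read DICOM series and RTSTRUCT files into geometry-aware objects.

Series slices are sorted by the projection of ImagePositionPatient onto the
slice normal (the cross product of the row and column direction cosines),
never by filename, so on-disk ordering is irrelevant.  Rescale slope and
intercept are applied on read.
"""

from __future__ import annotations

import fnmatch
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk

from .grid import BinaryMask, GridGeometry, ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "PlanarContour",
    "RoiContour",
    "StructureSet",
    "CasePairing",
    "read_series",
    "read_structset",
    "match_cases",
    "select_rois",
    "read_volume_nrrd",
    "read_mask_nrrd",
]

_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_GAP_TOL_MM = 1e-3


@dataclass(frozen=True)
class PlanarContour:
    points: np.ndarray  # (N, 3) patient mm, N >= 3


@dataclass
class RoiContour:
    name: str
    roi_number: int
    contours: list[PlanarContour]


@dataclass
class StructureSet:
    rois: list[RoiContour]
    referenced_series_uid: str = ""
    referenced_frame_of_reference_uid: str = ""
    source_file: Path | None = None

    def roi_names(self) -> list[str]:
        return [r.name for r in self.rois]


@dataclass(frozen=True)
class CasePairing:
    series_dir: Path
    rtstruct_path: Path
    matched_by: str  # frame_of_reference | series_uid | directory_fallback


def _normalize_roi_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip())


# ---------------------------------------------------------------------------
# series reading


def read_series(series_dir) -> ImageVolume:
    """Read a single-series directory of image-storage DICOM files."""
    series_dir = Path(series_dir)
    files = sorted(p for p in series_dir.iterdir() if p.suffix.lower() == ".dcm")
    datasets = []
    for f in files:
        ds = pydicom.dcmread(f)
        if ds.SOPClassUID == _RTSTRUCT_SOP_CLASS or "PixelData" not in ds:
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"no image-storage DICOM files in {series_dir}")

    uids = sorted({ds.SeriesInstanceUID for ds in datasets})
    if len(uids) > 1:
        raise ValueError(f"directory mixes {len(uids)} series: {', '.join(uids)}")

    first = datasets[0]
    for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        if tag not in first:
            raise ValueError(f"missing geometry tag {tag}")

    iop = np.asarray(first.ImageOrientationPatient, dtype=float)
    col_cos, row_cos = iop[:3], iop[3:]  # row value change along columns first
    normal = np.cross(col_cos, row_cos)
    datasets.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))

    positions = np.array([ds.ImagePositionPatient for ds in datasets], dtype=float)
    if len(datasets) > 1:
        deltas = np.diff(positions, axis=0)
        gaps = np.linalg.norm(deltas, axis=1)
        proj = deltas @ normal
        if np.any(np.abs(proj) < 1e-9):
            raise ValueError("duplicate or non-monotone slice positions along the normal")
        if gaps.max() - gaps.min() > _GAP_TOL_MM:
            raise ValueError(f"non-uniform slice gaps: {np.round(gaps, 4).tolist()} mm")
        slice_spacing = float(gaps.mean())
        slice_dir = deltas.mean(axis=0) / slice_spacing
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0) or 1.0)
        slice_dir = normal

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    ps = [float(x) for x in first.PixelSpacing]  # [row, col]
    direction = np.column_stack([slice_dir, row_cos, col_cos])
    geom = GridGeometry(tuple(positions[0]), (slice_spacing, ps[0], ps[1]), direction)
    return ImageVolume(
        voxels=voxels,
        geometry=geom,
        modality=str(getattr(first, "Modality", "")),
        patient_id=str(getattr(first, "PatientID", "")),
        series_uid=str(first.SeriesInstanceUID),
        frame_of_reference_uid=str(getattr(first, "FrameOfReferenceUID", "")),
    )


# ---------------------------------------------------------------------------
# RTSTRUCT reading


def read_structset(path) -> StructureSet:
    path = Path(path)
    ds = pydicom.dcmread(path)
    if ds.SOPClassUID != _RTSTRUCT_SOP_CLASS:
        raise ValueError(f"{path} is not an RT Structure Set (SOP class {ds.SOPClassUID})")

    names: dict[int, str] = {}
    for item in getattr(ds, "StructureSetROISequence", []):
        names[int(item.ROINumber)] = _normalize_roi_name(str(item.ROIName))

    rois: list[RoiContour] = []
    seen: set[str] = set()
    for item in getattr(ds, "ROIContourSequence", []):
        num = int(item.ReferencedROINumber)
        name = names.get(num, f"roi-{num}")
        if name.lower() in seen:
            raise ValueError(f"duplicate ROI name after normalization: {name!r}")
        seen.add(name.lower())
        contours = []
        for c in getattr(item, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if len(pts) < 3:
                log.warning("dropping degenerate %d-point contour in ROI %r", len(pts), name)
                continue
            contours.append(PlanarContour(points=pts))
        rois.append(RoiContour(name=name, roi_number=num, contours=contours))

    ref_series, ref_for = "", ""
    for frame in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        ref_for = str(getattr(frame, "FrameOfReferenceUID", "")) or ref_for
        for study in getattr(frame, "RTReferencedStudySequence", []):
            for series in getattr(study, "RTReferencedSeriesSequence", []):
                ref_series = str(getattr(series, "SeriesInstanceUID", "")) or ref_series
    return StructureSet(
        rois=rois,
        referenced_series_uid=ref_series,
        referenced_frame_of_reference_uid=ref_for,
        source_file=path,
    )


# ---------------------------------------------------------------------------
# case matching


def _is_rtstruct(path: Path) -> bool:
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True, specific_tags=["SOPClassUID"])
    except Exception:
        return False
    return str(getattr(ds, "SOPClassUID", "")) == _RTSTRUCT_SOP_CLASS


def _scan(root: Path):
    """Find series directories and RTSTRUCT files under root."""
    series: dict[Path, dict] = {}
    rtstructs: list[dict] = []
    for path in sorted(root.rglob("*.dcm")):
        if _is_rtstruct(path):
            ss = read_structset(path)
            rtstructs.append(
                {
                    "path": path,
                    "for_uid": ss.referenced_frame_of_reference_uid,
                    "series_uid": ss.referenced_series_uid,
                }
            )
            continue
        d = path.parent
        if d in series:
            continue
        try:
            ds = pydicom.dcmread(
                path,
                stop_before_pixels=True,
                specific_tags=["SeriesInstanceUID", "FrameOfReferenceUID"],
            )
        except Exception:
            continue
        series[d] = {
            "dir": d,
            "series_uid": str(getattr(ds, "SeriesInstanceUID", "")),
            "for_uid": str(getattr(ds, "FrameOfReferenceUID", "")),
        }
    return list(series.values()), rtstructs


def match_cases(root) -> list[CasePairing]:
    """Pair every RTSTRUCT with its image series.

    Precedence: shared FrameOfReferenceUID, then referenced SeriesInstanceUID,
    then co-location under the same case directory.  Unmatched items are
    logged, never fatal.
    """
    root = Path(root)
    all_series, rtstructs = _scan(root)
    pairings: list[CasePairing] = []
    for rt in rtstructs:
        matched = [s for s in all_series if rt["for_uid"] and s["for_uid"] == rt["for_uid"]]
        how = "frame_of_reference"
        if not matched:
            matched = [
                s for s in all_series if rt["series_uid"] and s["series_uid"] == rt["series_uid"]
            ]
            how = "series_uid"
        if not matched:
            case_dir = rt["path"].parent
            matched = [s for s in all_series if case_dir in s["dir"].parents or s["dir"] == case_dir]
            how = "directory_fallback"
            if matched:
                log.warning("RTSTRUCT %s matched by directory fallback only", rt["path"])
        if not matched:
            log.warning("RTSTRUCT %s matched no series; skipped", rt["path"])
            continue
        if len(matched) > 1:
            log.warning("RTSTRUCT %s matches %d series; emitting all", rt["path"], len(matched))
        for s in matched:
            pairings.append(
                CasePairing(series_dir=s["dir"], rtstruct_path=rt["path"], matched_by=how)
            )
    claimed = {}
    for p in pairings:
        claimed.setdefault(p.series_dir, []).append(p.rtstruct_path)
    for d, rts in claimed.items():
        if len(rts) > 1:
            log.warning("series %s claimed by %d RTSTRUCTs", d, len(rts))
    return pairings


def select_rois(ss: StructureSet, include=(), exclude=()) -> StructureSet:
    """Case-insensitive glob filter; exclude wins; empty include means all."""

    def hits(name: str, patterns) -> bool:
        return any(fnmatch.fnmatch(name.lower(), p.lower()) for p in patterns)

    kept = [
        r
        for r in ss.rois
        if (not include or hits(r.name, include)) and not hits(r.name, exclude)
    ]
    return StructureSet(
        rois=kept,
        referenced_series_uid=ss.referenced_series_uid,
        referenced_frame_of_reference_uid=ss.referenced_frame_of_reference_uid,
        source_file=ss.source_file,
    )


# ---------------------------------------------------------------------------
# NRRD bypass path


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, GridGeometry]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    sp = img.GetSpacing()  # (x, y, z)
    d = np.asarray(img.GetDirection()).reshape(3, 3)  # columns x,y,z axes
    direction = np.column_stack([d[:, 2], d[:, 1], d[:, 0]])  # -> slice,row,col
    geom = GridGeometry(tuple(img.GetOrigin()), (sp[2], sp[1], sp[0]), direction)
    return arr, geom


def read_volume_nrrd(path, modality: str = "", patient_id: str = "") -> ImageVolume:
    arr, geom = _from_sitk(sitk.ReadImage(str(path)))
    return ImageVolume(
        voxels=arr.astype(np.float64),
        geometry=geom,
        modality=modality,
        patient_id=patient_id,
    )


def read_mask_nrrd(path, roi_name: str = "mask") -> BinaryMask:
    arr, geom = _from_sitk(sitk.ReadImage(str(path)))
    return BinaryMask(bits=arr > 0, roi_name=roi_name, grid_ref=geom)
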