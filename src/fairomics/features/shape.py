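"""Morphological (shape) features: 14 features.

The surface is a triangulated 0.5 iso-surface of the mask indicator
(marching cubes on the zero-padded mask).  The indicator is smoothed with
a narrow Gaussian (sigma = 0.8 voxels) before meshing: marching cubes on
raw binary data inherits the voxel staircase and overestimates the area
of smooth solids by roughly 8-9%, while the smoothed iso-surface is
accurate to well under 1% on analytic spheres.  Structures so thin that
smoothing would sink them below the iso-level fall back to the raw binary
surface.  Mesh volume comes from the
divergence theorem over the triangle fan; axis lengths are ``4 * sqrt(λ)``
with λ the eigenvalues of the population covariance of the physical
voxel-center coordinates.  Maximum 2-D diameters are measured on surface
vertices projected onto the three grid planes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes, mesh_surface_area

from ..grid import BinaryMask
from .base import FeatureResult, nan_result

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
    "Mesh Volume",
    "Voxel Volume",
    "Surface Area",
    "Surface Volume Ratio",
    "Sphericity",
    "Maximum 3D Diameter",
    "Maximum 2D Diameter (Slice)",
    "Maximum 2D Diameter (Column)",
    "Maximum 2D Diameter (Row)",
    "Major Axis Length",
    "Minor Axis Length",
    "Least Axis Length",
    "Elongation",
    "Flatness",
)

_MESH_NAMES = SHAPE_NAMES[:9]  # surface/mesh-derived subset


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise distance, via convex-hull vertices, chunked."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > points.shape[1] + 1:
        try:
            pts = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (flat) point sets
            pass
    best = 0.0
    for i in range(0, len(pts), 512):
        chunk = pts[i : i + 512]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def shape_features(mask: BinaryMask) -> list[FeatureResult]:
    n = mask.voxel_count
    if n == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(mask.grid_ref.spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))

    out: list[FeatureResult] = []
    if n >= 2:
        padded = np.pad(mask.bits, 2).astype(float)
        field = gaussian_filter(padded, sigma=0.8)
        if field.max() <= 0.55:  # thin structure: smoothing would erase it
            field = padded
        verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=tuple(spacing))
        tri = verts[faces]
        mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
        area = float(mesh_surface_area(verts, faces))
        sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area
        mesh_vals = {
            "Mesh Volume": mesh_volume,
            "Voxel Volume": n * voxel_volume,
            "Surface Area": area,
            "Surface Volume Ratio": area / mesh_volume,
            "Sphericity": sphericity,
            "Maximum 3D Diameter": _max_pairwise(verts),
            "Maximum 2D Diameter (Slice)": _max_pairwise(verts[:, [1, 2]]),
            "Maximum 2D Diameter (Column)": _max_pairwise(verts[:, [0, 1]]),
            "Maximum 2D Diameter (Row)": _max_pairwise(verts[:, [0, 2]]),
        }
        units = {"Mesh Volume": "mm3", "Voxel Volume": "mm3", "Surface Area": "mm2"}
        for name in _MESH_NAMES:
            out.append(
                FeatureResult(
                    "shape", name, mesh_vals[name],
                    units=units.get(name, "mm" if "Diameter" in name else ""),
                )
            )
    else:
        for name in _MESH_NAMES:
            if name == "Voxel Volume":
                out.append(FeatureResult("shape", name, n * voxel_volume, units="mm3"))
            else:
                out.append(nan_result("shape", name, "single-voxel mask has a degenerate mesh"))

    coords = np.argwhere(mask.bits).astype(float) * spacing
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1].clip(min=0.0)
    lengths = 4.0 * np.sqrt(eigvals)
    for name, val in zip(("Major Axis Length", "Minor Axis Length", "Least Axis Length"), lengths):
        out.append(FeatureResult("shape", name, float(val), units="mm"))
    if eigvals[0] > 0:
        out.append(FeatureResult("shape", "Elongation", float(np.sqrt(eigvals[1] / eigvals[0]))))
        out.append(FeatureResult("shape", "Flatness", float(np.sqrt(eigvals[2] / eigvals[0]))))
    else:
        out.append(nan_result("shape", "Elongation", "degenerate principal axes"))
        out.append(nan_result("shape", "Flatness", "degenerate principal axes"))
    return out
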