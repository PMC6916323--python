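"""Gray-level size-zone matrix features: 16 features.

A zone is a 26-connected component of equal-level voxels; the size-zone
matrix counts zones by (gray level, zone size).  Unlike run-length
features there is no direction to average over.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedRegion
from .base import FeatureResult, nan_result
from .glrlm import _GENERIC, size_matrix_features

__all__ = ["glszm_matrix", "glszm_features", "GLSZM_NAMES"]

GLSZM_NAMES = (
    "Small Area Emphasis",
    "Large Area Emphasis",
    "Gray Level Non-Uniformity",
    "Gray Level Non-Uniformity Normalized",
    "Size-Zone Non-Uniformity",
    "Size-Zone Non-Uniformity Normalized",
    "Zone Percentage",
    "Gray Level Variance",
    "Zone Variance",
    "Zone Entropy",
    "Low Gray Level Zone Emphasis",
    "High Gray Level Zone Emphasis",
    "Small Area Low Gray Level Emphasis",
    "Small Area High Gray Level Emphasis",
    "Large Area Low Gray Level Emphasis",
    "Large Area High Gray Level Emphasis",
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(d: DiscretizedRegion) -> np.ndarray:
    """Size-zone count matrix (Ng x Smax)."""
    zones: list[tuple[int, int]] = []
    for level in range(1, d.ng + 1):
        labels, n = ndimage.label(d.level_grid == level, structure=_STRUCT26)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    if not zones:
        return np.zeros((max(d.ng, 1), 1))
    smax = max(s for _, s in zones)
    mat = np.zeros((d.ng, smax), dtype=float)
    for level, s in zones:
        mat[level - 1, s - 1] += 1.0
    return mat


def glszm_features(d: DiscretizedRegion) -> list[FeatureResult]:
    if d.n_voxels == 0:
        return [nan_result("glszm", name, "empty region") for name in GLSZM_NAMES]
    feats = size_matrix_features(glszm_matrix(d), d.n_voxels)
    return [
        FeatureResult("glszm", name, feats[key]) for name, key in zip(GLSZM_NAMES, _GENERIC)
    ]
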