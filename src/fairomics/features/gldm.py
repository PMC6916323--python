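"""Gray-level dependence matrix features: 14 features.

For each masked voxel the dependence count is the number of its 26
neighbors (inside the mask) whose level differs by at most ``alpha``
(default 0).  The matrix is indexed (gray level, dependence + 1), so an
isolated voxel contributes to column 1 and a fully surrounded voxel in a
constant region to column 27.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedRegion
from .base import ANGLES_26, FeatureResult, entropy_bits, nan_result

__all__ = ["gldm_matrix", "gldm_features", "GLDM_NAMES"]

GLDM_NAMES = (
    "Small Dependence Emphasis",
    "Large Dependence Emphasis",
    "Gray Level Non-Uniformity",
    "Dependence Non-Uniformity",
    "Dependence Non-Uniformity Normalized",
    "Gray Level Variance",
    "Dependence Variance",
    "Dependence Entropy",
    "Low Gray Level Emphasis",
    "High Gray Level Emphasis",
    "Small Dependence Low Gray Level Emphasis",
    "Small Dependence High Gray Level Emphasis",
    "Large Dependence Low Gray Level Emphasis",
    "Large Dependence High Gray Level Emphasis",
)


def _neighbor_stats(d: DiscretizedRegion, alpha: int):
    """Per-voxel dependence counts (and neighbor sums/counts for reuse)."""
    lg, mask = d.level_grid, d.mask
    dep = np.zeros(lg.shape, dtype=np.int64)
    for off in ANGLES_26:
        dk, dr, dc = (int(x) for x in off)
        shifted_lv = np.full(lg.shape, -(10**9), dtype=np.int64)
        shifted_mask = np.zeros(lg.shape, dtype=bool)
        src = tuple(
            slice(max(0, -s), lg.shape[ax] - max(0, s)) for ax, s in enumerate((dk, dr, dc))
        )
        dst = tuple(
            slice(max(0, s), lg.shape[ax] - max(0, -s)) for ax, s in enumerate((dk, dr, dc))
        )
        shifted_lv[dst] = lg[src]
        shifted_mask[dst] = mask[src]
        dep += (shifted_mask & (np.abs(shifted_lv - lg) <= alpha)) & mask
    return dep


def gldm_matrix(d: DiscretizedRegion, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (Ng x 27): column j holds dependence j-1."""
    dep = _neighbor_stats(d, alpha)
    levels = d.level_grid[d.mask]
    deps = dep[d.mask]
    mat = np.zeros((d.ng, 27), dtype=float)
    np.add.at(mat, (levels - 1, deps), 1.0)
    # trim trailing all-zero dependence columns (keeps formulas identical)
    last = int(deps.max()) + 1 if deps.size else 1
    return mat[:, :last]


def gldm_features(d: DiscretizedRegion, alpha: int = 0) -> list[FeatureResult]:
    if d.n_voxels == 0:
        return [nan_result("gldm", name, "empty region") for name in GLDM_NAMES]
    counts = gldm_matrix(d, alpha)
    nz = counts.sum()  # equals the voxel count: every voxel has one dependence
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]  # dependence + 1
    p = counts / nz
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    vals = {
        "Small Dependence Emphasis": float((counts / j**2).sum() / nz),
        "Large Dependence Emphasis": float((counts * j**2).sum() / nz),
        "Gray Level Non-Uniformity": float((counts.sum(axis=1) ** 2).sum() / nz),
        "Dependence Non-Uniformity": float((counts.sum(axis=0) ** 2).sum() / nz),
        "Dependence Non-Uniformity Normalized": float((counts.sum(axis=0) ** 2).sum() / nz**2),
        "Gray Level Variance": float((p * (i - mu_i) ** 2).sum()),
        "Dependence Variance": float((p * (j - mu_j) ** 2).sum()),
        "Dependence Entropy": entropy_bits(p.ravel()),
        "Low Gray Level Emphasis": float((counts / i**2).sum() / nz),
        "High Gray Level Emphasis": float((counts * i**2).sum() / nz),
        "Small Dependence Low Gray Level Emphasis": float((counts / (i**2 * j**2)).sum() / nz),
        "Small Dependence High Gray Level Emphasis": float((counts * i**2 / j**2).sum() / nz),
        "Large Dependence Low Gray Level Emphasis": float((counts * j**2 / i**2).sum() / nz),
        "Large Dependence High Gray Level Emphasis": float((counts * i**2 * j**2).sum() / nz),
    }
    return [FeatureResult("gldm", name, vals[name]) for name in GLDM_NAMES]
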