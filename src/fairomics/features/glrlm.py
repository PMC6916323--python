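"""Gray-level run-length matrix features: 16 features.

A run is a maximal collinear segment of equal-level voxels.  Runs are
enumerated along the 13 unique 3-D directions; features are computed per
direction and averaged with equal weights.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedRegion
from .base import ANGLES_13, FeatureResult, entropy_bits, nan_result

__all__ = ["glrlm_matrix", "glrlm_features", "size_matrix_features", "GLRLM_NAMES"]

GLRLM_NAMES = (
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Gray Level Non-Uniformity",
    "Gray Level Non-Uniformity Normalized",
    "Run Length Non-Uniformity",
    "Run Length Non-Uniformity Normalized",
    "Run Percentage",
    "Gray Level Variance",
    "Run Variance",
    "Run Entropy",
    "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis",
    "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis",
    "Long Run High Gray Level Emphasis",
)

# generic (gray level, size) feature keys shared with the size-zone family
_GENERIC = (
    "small",
    "large",
    "gln",
    "glnn",
    "sn",
    "snn",
    "pct",
    "glv",
    "sv",
    "entropy",
    "lgl",
    "hgl",
    "small_lgl",
    "small_hgl",
    "large_lgl",
    "large_hgl",
)


def _in_bounds(idx: np.ndarray, shape) -> np.ndarray:
    return np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)


def glrlm_matrix(d: DiscretizedRegion, direction) -> np.ndarray:
    """Run-length count matrix (Ng x Lmax) for one direction."""
    lg, mask = d.level_grid, d.mask
    dvec = np.asarray(direction, dtype=int)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.zeros((d.ng, 1))
    prev = idx - dvec
    ok = _in_bounds(prev, lg.shape)
    cont = np.zeros(len(idx), dtype=bool)
    if ok.any():
        pk = prev[ok]
        cont[ok] = mask[pk[:, 0], pk[:, 1], pk[:, 2]] & (
            lg[pk[:, 0], pk[:, 1], pk[:, 2]] == lg[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        )
    starts = idx[~cont]
    levels = lg[starts[:, 0], starts[:, 1], starts[:, 2]]
    lengths = np.ones(len(starts), dtype=int)

    cur = starts.copy()
    alive = np.arange(len(starts))
    while alive.size:
        nxt = cur + dvec
        ok = _in_bounds(nxt, lg.shape)
        if ok.any():
            nk = nxt[ok]
            ok[ok.nonzero()[0]] = mask[nk[:, 0], nk[:, 1], nk[:, 2]] & (
                lg[nk[:, 0], nk[:, 1], nk[:, 2]] == levels[alive[ok]]
            )
        lengths[alive[ok]] += 1
        alive, cur = alive[ok], nxt[ok]

    mat = np.zeros((d.ng, int(lengths.max())), dtype=float)
    np.add.at(mat, (levels - 1, lengths - 1), 1.0)
    return mat


def size_matrix_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Shared formulas over a (gray level, run length / zone size) matrix."""
    ns = counts.sum()
    if ns == 0:
        return {k: float("nan") for k in _GENERIC}
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    p = counts / ns
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "small": float((counts / j**2).sum() / ns),
        "large": float((counts * j**2).sum() / ns),
        "gln": float((counts.sum(axis=1) ** 2).sum() / ns),
        "glnn": float((counts.sum(axis=1) ** 2).sum() / ns**2),
        "sn": float((counts.sum(axis=0) ** 2).sum() / ns),
        "snn": float((counts.sum(axis=0) ** 2).sum() / ns**2),
        "pct": float(ns / n_voxels),
        "glv": float((p * (i - mu_i) ** 2).sum()),
        "sv": float((p * (j - mu_j) ** 2).sum()),
        "entropy": entropy_bits(p.ravel()),
        "lgl": float((counts / i**2).sum() / ns),
        "hgl": float((counts * i**2).sum() / ns),
        "small_lgl": float((counts / (i**2 * j**2)).sum() / ns),
        "small_hgl": float((counts * i**2 / j**2).sum() / ns),
        "large_lgl": float((counts * j**2 / i**2).sum() / ns),
        "large_hgl": float((counts * i**2 * j**2).sum() / ns),
    }


def glrlm_features(d: DiscretizedRegion) -> list[FeatureResult]:
    if d.n_voxels == 0:
        return [nan_result("glrlm", name, "empty region") for name in GLRLM_NAMES]
    per_dir = [size_matrix_features(glrlm_matrix(d, a), d.n_voxels) for a in ANGLES_13]
    return [
        FeatureResult("glrlm", name, float(np.mean([f[key] for f in per_dir])))
        for name, key in zip(GLRLM_NAMES, _GENERIC)
    ]
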