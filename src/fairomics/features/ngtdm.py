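"""Neighborhood gray-tone difference matrix features: 5 features.

For gray level i, ``s_i`` sums |i - A| over masked voxels of level i,
where A is the mean level of the voxel's masked 26-neighbors.  Voxels with
no masked neighbor do not participate.  ``p_i`` is the fraction of
participating voxels at level i.  Division-by-zero guards use eps = 1e-6
so degenerate (constant) regions stay deterministic: Coarseness caps at
1e6, Contrast/Busyness/Strength fall back to 0.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedRegion
from .base import ANGLES_26, FeatureResult, nan_result

__all__ = ["ngtdm_table", "ngtdm_features", "NGTDM_NAMES"]

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EPS = 1e-6


def ngtdm_table(d: DiscretizedRegion) -> np.ndarray:
    """Rows (level 1..Ng): n_i, p_i, s_i over participating voxels."""
    lg, mask = d.level_grid, d.mask
    nb_sum = np.zeros(lg.shape, dtype=float)
    nb_cnt = np.zeros(lg.shape, dtype=np.int64)
    for off in ANGLES_26:
        dk, dr, dc = (int(x) for x in off)
        src = tuple(
            slice(max(0, -s), lg.shape[ax] - max(0, s)) for ax, s in enumerate((dk, dr, dc))
        )
        dst = tuple(
            slice(max(0, s), lg.shape[ax] - max(0, -s)) for ax, s in enumerate((dk, dr, dc))
        )
        nb_sum[dst] += np.where(mask[src], lg[src], 0)
        nb_cnt[dst] += mask[src]
    part = mask & (nb_cnt > 0)
    table = np.zeros((d.ng, 3), dtype=float)
    if not part.any():
        return table
    levels = lg[part]
    diffs = np.abs(levels - nb_sum[part] / nb_cnt[part])
    n_part = int(part.sum())
    for level in range(1, d.ng + 1):
        sel = levels == level
        table[level - 1, 0] = sel.sum()
        table[level - 1, 2] = diffs[sel].sum()
    table[:, 1] = table[:, 0] / n_part
    return table


def ngtdm_features(d: DiscretizedRegion) -> list[FeatureResult]:
    table = ngtdm_table(d)
    n_vec, p_vec, s_vec = table[:, 0], table[:, 1], table[:, 2]
    nvp = n_vec.sum()
    if nvp == 0:
        return [nan_result("ngtdm", name, "no voxel has a masked neighbor") for name in NGTDM_NAMES]
    i = np.arange(1, d.ng + 1, dtype=float)
    act = p_vec > 0
    ngp = int(act.sum())
    ia, pa, sa = i[act], p_vec[act], s_vec[act]

    coarseness = 1.0 / max(float((p_vec * s_vec).sum()), _EPS)
    coarseness = min(coarseness, 1.0 / _EPS)

    if ngp > 1:
        di2 = (ia[:, None] - ia[None, :]) ** 2
        contrast = float(
            (pa[:, None] * pa[None, :] * di2).sum() / (ngp * (ngp - 1)) * (s_vec.sum() / nvp)
        )
        busy_den = float(np.abs(ia[:, None] * pa[:, None] - ia[None, :] * pa[None, :]).sum())
        busyness = float((p_vec * s_vec).sum() / busy_den) if busy_den > _EPS else 0.0
    else:
        contrast, busyness = 0.0, 0.0

    pis = pa * sa
    complexity = float(
        (np.abs(ia[:, None] - ia[None, :]) * (pis[:, None] + pis[None, :])
         / (pa[:, None] + pa[None, :])).sum() / nvp
    )
    s_total = float(s_vec.sum())
    if s_total > _EPS:
        strength = float(((pa[:, None] + pa[None, :]) * (ia[:, None] - ia[None, :]) ** 2).sum() / s_total)
    else:
        strength = 0.0

    vals = {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    return [FeatureResult("ngtdm", name, vals[name]) for name in NGTDM_NAMES]
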