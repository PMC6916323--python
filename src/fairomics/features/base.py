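"""Shared containers and grid utilities for the feature families."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("fairomics.features")

__all__ = ["FeatureResult", "ANGLES_13", "ANGLES_26", "entropy_bits", "nan_result"]


@dataclass(frozen=True)
class FeatureResult:
    family: str
    name: str
    value: float
    units: str = ""
    ibsi_code: str | None = None
    config_fingerprint: str = ""

    def with_fingerprint(self, fp: str) -> "FeatureResult":
        return FeatureResult(self.family, self.name, self.value, self.units, self.ibsi_code, fp)


def _unique_angles() -> np.ndarray:
    """The 13 unique direction vectors of the 26-neighborhood (distance 1)."""
    out = []
    for dk in (-1, 0, 1):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                v = (dk, dr, dc)
                if v == (0, 0, 0):
                    continue
                if v > (0, 0, 0):  # keep one of each ±pair
                    out.append(v)
    return np.array(out, dtype=int)


ANGLES_13 = _unique_angles()
ANGLES_26 = np.concatenate([ANGLES_13, -ANGLES_13])


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits over nonzero probabilities."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0) if p.size else 0.0


def nan_result(family: str, name: str, reason: str, units: str = "") -> FeatureResult:
    log.info("%s/%s is NaN: %s", family, name, reason)
    return FeatureResult(family=family, name=name, value=float("nan"), units=units)


def shifted_pairs(level_grid: np.ndarray, mask: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Levels of all valid (voxel, voxel+offset) pairs, both inside the mask."""
    dk, dr, dc = (int(x) for x in offset)
    sl_a, sl_b = [], []
    for d, n in zip((dk, dr, dc), level_grid.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    return level_grid[sl_a][valid], level_grid[sl_b][valid]
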