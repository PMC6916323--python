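"""Gray-level co-occurrence matrix features: 22 features.

One symmetric GLCM is accumulated per unique 3-D direction (distance 1,
13 directions), normalized to probabilities, and the 22 scalar features
are computed per direction then averaged with equal weights.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedRegion
from .base import ANGLES_13, FeatureResult, entropy_bits, nan_result, shifted_pairs

__all__ = ["glcm_matrices", "glcm_features", "glcm_features_single", "GLCM_NAMES"]

GLCM_NAMES = (
    "Autocorrelation",
    "Joint Average",
    "Cluster Prominence",
    "Cluster Shade",
    "Cluster Tendency",
    "Contrast",
    "Correlation",
    "Difference Average",
    "Difference Entropy",
    "Difference Variance",
    "Joint Energy",
    "Joint Entropy",
    "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2",
    "Inverse Difference Moment",
    "Inverse Difference Moment Normalized",
    "Inverse Difference",
    "Inverse Difference Normalized",
    "Inverse Variance",
    "Maximum Probability",
    "Sum Entropy",
    "Sum of Squares",
)


def glcm_matrices(d: DiscretizedRegion, distance: int = 1) -> list[np.ndarray]:
    """Per-direction symmetric co-occurrence count matrices (Ng x Ng)."""
    ng = d.ng
    mats = []
    for angle in ANGLES_13 * distance:
        a, b = shifted_pairs(d.level_grid, d.mask, angle)
        m = np.zeros((ng, ng), dtype=float)
        if a.size:
            np.add.at(m, (a - 1, b - 1), 1.0)
            np.add.at(m, (b - 1, a - 1), 1.0)
        mats.append(m)
    return mats


def glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    """The 22 features from one co-occurrence count (or probability) matrix."""
    total = counts.sum()
    if total == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) marginals
    kd = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)
    da = float((kd * p_diff).sum())

    hxy = entropy_bits(p.ravel())
    hx, hy = entropy_bits(px), entropy_bits(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log2(outer[nz])).sum())
    nzo = outer > 0
    hxy2 = float(-(outer[nzo] * np.log2(outer[nzo])).sum())

    if sig_x > 0 and sig_y > 0:
        correlation = (float((p * ii * jj).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0  # flat region: perfectly predictable co-occurrence
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "Joint Average": mu_x,
        "Cluster Prominence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "Cluster Shade": float((p * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "Cluster Tendency": float((p * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": float(correlation),
        "Difference Average": da,
        "Difference Entropy": entropy_bits(p_diff),
        "Difference Variance": float((p_diff * (kd - da) ** 2).sum()),
        "Joint Energy": float((p**2).sum()),
        "Joint Entropy": hxy,
        "Informational Measure of Correlation 1": float(imc1),
        "Informational Measure of Correlation 2": imc2,
        "Inverse Difference Moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Inverse Difference Moment Normalized": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Inverse Difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Inverse Difference Normalized": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Inverse Variance": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "Maximum Probability": float(p.max()),
        "Sum Entropy": entropy_bits(p_sum),
        "Sum of Squares": float((p * (ii - mu_x) ** 2).sum()),
    }


def glcm_features(d: DiscretizedRegion, distance: int = 1) -> list[FeatureResult]:
    mats = [m for m in glcm_matrices(d, distance) if m.sum() > 0]
    if not mats:
        return [nan_result("glcm", name, "no valid neighbor pairs") for name in GLCM_NAMES]
    per_dir = [glcm_features_single(m) for m in mats]
    return [
        FeatureResult("glcm", name, float(np.mean([f[name] for f in per_dir])))
        for name in GLCM_NAMES
    ]
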