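"""First-order (intensity) statistics: 18 features.

Histogram-based features (Entropy, Uniformity) use the discretized levels;
all other statistics use the raw masked intensities.  Variance is the
population (biased) form and Kurtosis is the non-excess Pearson form, so a
normal distribution scores 3, not 0.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedRegion
from .base import FeatureResult, entropy_bits, nan_result

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy",
    "Total Energy",
    "Entropy",
    "Minimum",
    "10th Percentile",
    "90th Percentile",
    "Maximum",
    "Mean",
    "Median",
    "Interquartile Range",
    "Range",
    "Mean Absolute Deviation",
    "Robust Mean Absolute Deviation",
    "Root Mean Squared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(d: DiscretizedRegion, raw_values: np.ndarray) -> list[FeatureResult]:
    x = np.asarray(raw_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty region")
    if x.size != d.n_voxels:
        raise ValueError("raw values and discretized region disagree on voxel count")

    p = d.histogram() / d.n_voxels
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())

    vals: dict[str, float] = {
        "Energy": energy,
        "Total Energy": energy * d.voxel_volume,
        "Entropy": entropy_bits(p),
        "Minimum": float(x.min()),
        "10th Percentile": p10,
        "90th Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "Interquartile Range": p75 - p25,
        "Range": float(x.max() - x.min()),
        "Mean Absolute Deviation": float(np.abs(x - mean).mean()),
        "Robust Mean Absolute Deviation": float(np.abs(robust - robust.mean()).mean()),
        "Root Mean Squared": float(np.sqrt((x**2).mean())),
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
    }

    out = [FeatureResult("firstorder", name, vals[name]) for name in FIRSTORDER_NAMES[:14]]
    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        out.append(FeatureResult("firstorder", "Skewness", m3 / m2**1.5))
        out.append(FeatureResult("firstorder", "Kurtosis", m4 / m2**2))
    else:
        out.append(nan_result("firstorder", "Skewness", "zero variance region"))
        out.append(nan_result("firstorder", "Kurtosis", "zero variance region"))
    out.append(FeatureResult("firstorder", "Variance", vals["Variance"]))
    out.append(FeatureResult("firstorder", "Uniformity", vals["Uniformity"]))
    return out
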