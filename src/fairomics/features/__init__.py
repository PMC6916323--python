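"""IBSI-aligned radiomic feature panel.

The default panel is 105 features across seven families:
first-order (18), shape (14), GLCM (22), GLRLM (16), GLSZM (16),
GLDM (14) and NGTDM (5).  Families can be switched individually through
:class:`~fairomics.preprocess.ExtractionConfig`; degenerate regions yield
NaN-valued results with a logged reason, never missing rows.
"""

from __future__ import annotations

from ..grid import BinaryMask, ImageVolume
from ..preprocess import ExtractionConfig, discretize, resample, resegment
from .base import FeatureResult
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .gldm import GLDM_NAMES, gldm_features
from .glcm import GLCM_NAMES, glcm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features
from .shape import SHAPE_NAMES, shape_features

__all__ = [
    "FeatureResult",
    "extract_all",
    "PANEL",
    "firstorder_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

#: family -> ordered feature names of the default 105-feature panel
PANEL = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def extract_all(
    vol: ImageVolume, mask: BinaryMask, cfg: ExtractionConfig | None = None
) -> list[FeatureResult]:
    """Run the enabled feature families on one VOI.

    Pipeline: optional resampling, optional intensity re-segmentation,
    gray-level discretization, then the family computations.  Every result
    is stamped with the configuration fingerprint.
    """
    cfg = cfg or ExtractionConfig()
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask.roi_name!r} is empty")
    if cfg.resample_spacing is not None:
        vol, mask = resample(vol, mask, cfg.resample_spacing)
    if cfg.reseg_range is not None:
        mask = resegment(vol, mask, cfg.reseg_range)
        if mask.voxel_count == 0:
            raise ValueError(f"re-segmentation removed every voxel of {mask.roi_name!r}")
    region = discretize(vol, mask, cfg)
    raw = vol.voxels[mask.bits]

    results: list[FeatureResult] = []
    for family in PANEL:
        if family not in cfg.enabled_families:
            continue
        if family == "firstorder":
            results.extend(firstorder_features(region, raw))
        elif family == "shape":
            results.extend(shape_features(mask))
        elif family == "glcm":
            results.extend(glcm_features(region))
        elif family == "glrlm":
            results.extend(glrlm_features(region))
        elif family == "glszm":
            results.extend(glszm_features(region))
        elif family == "gldm":
            results.extend(gldm_features(region, alpha=cfg.gldm_alpha))
        elif family == "ngtdm":
            results.extend(ngtdm_features(region))
    fp = cfg.fingerprint()
    return [r.with_fingerprint(fp) for r in results]
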