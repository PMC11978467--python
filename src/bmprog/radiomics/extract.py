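"""Composition of the 107-feature radiomic vector for one lesion ROI.

Feature classes and counts: shape (14), first-order (18), GLCM (24),
GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5) — 107 named scalars, computed
on the image restricted to the lesion mask with a fixed 64-bin gray-level
discretization for the histogram/texture features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .firstorder import FIRSTORDER_FEATURES, firstorder_features
from .preprocess import ImageVolume, MaskVolume
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    gray_level_volume,
    ngtdm_features,
)

_CLASS_FEATURES = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"original_{cls}_{name}"
    for cls, names in _CLASS_FEATURES.items()
    for name in names
)
assert len(FEATURE_NAMES) == 107


def extractor_settings(bin_count: int = 64, target_spacing_mm: float = 0.5) -> dict:
    """Serializable provenance of the extraction configuration."""
    return {
        "discretization": {"mode": "fixed_bin_count", "bin_count": bin_count},
        "resampling": {"target_spacing_mm": [target_spacing_mm] * 3},
        "normalization": {"mode": "brain_zscore", "clip_sd": 3.0},
        "feature_classes": {cls: len(names) for cls, names in _CLASS_FEATURES.items()},
        "n_features": len(FEATURE_NAMES),
    }


def extract_features(
    image: ImageVolume, lesion_mask: MaskVolume, bin_count: int = 64
) -> pd.Series:
    """Extract the 107-feature vector from the lesion ROI.

    The image is expected to be resampled and normalized already; determinism
    for a fixed input is exact (no stochastic steps).
    """
    if image.data.shape != lesion_mask.data.shape:
        raise ValueError("image and mask are not on the same grid")
    mask = lesion_mask.data
    if not mask.any():
        raise ValueError("empty lesion mask")

    # crop to the mask bounding box (texture features are translation-invariant)
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_img = image.data[box].astype(float)
    sub_mask = mask[box]

    voxel_volume = float(np.prod(image.spacing))
    values = sub_img[sub_mask]
    disc = discretize(values, bin_count)
    gl = np.zeros(sub_mask.shape, dtype=np.int64)
    gl[sub_mask] = disc

    out: dict[str, float] = {}
    per_class = {
        "shape": shape_features(mask, image.spacing),
        "firstorder": firstorder_features(values, disc, voxel_volume),
        "glcm": glcm_features(gl),
        "glrlm": glrlm_features(gl),
        "glszm": glszm_features(gl),
        "gldm": gldm_features(gl),
        "ngtdm": ngtdm_features(gl),
    }
    for cls, names in _CLASS_FEATURES.items():
        feats = per_class[cls]
        for name in names:
            out[f"original_{cls}_{name}"] = float(feats[name])
    return pd.Series(out, index=list(FEATURE_NAMES), name="features")
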