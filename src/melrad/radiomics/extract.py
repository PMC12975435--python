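"""Per-patient feature extraction against a registry.

The full vector pairs every intensity/texture class with the original SUV
volume and each of the 8 stationary coif1 sub-bands; shape and the
supplementary first-order features are computed on the original only.
Discretization is applied independently per image type with the same fixed
bin width, anchored at each image's in-mask minimum. The volume is cropped
to the mask bounding box (with a margin covering the wavelet filter
support) before the transform, purely for speed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..segmentation import SuvVolume
from .discretize import DEFAULT_BIN_WIDTH, discretize_volume
from .firstorder import first_order_extras, first_order_features
from .registry import FeatureRegistry, default_registry
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .wavelet import wavelet_decompose

__all__ = ["extract_features"]

_CROP_MARGIN = 12  # > coif1 filter support, so boundary effects stay local


def _crop_to_mask(data: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - _CROP_MARGIN, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + _CROP_MARGIN, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return data[sl], mask[sl]


def _class_features(image, mask, bin_width, gldm_alpha, voxel_volume=1.0):
    region = discretize_volume(image, mask, bin_width)
    values = image[mask]
    out = {}
    out["FirstOrder"] = first_order_features(
        values, voxel_volume=voxel_volume, bin_width=bin_width
    )
    out["GrayLevelCooccurrenceMatrix"] = glcm_features(region)
    out["GrayLevelRunLengthMatrix"] = glrlm_features(region)
    out["GrayLevelSizeZoneMatrix"] = glszm_features(region)
    out["GrayLevelDependenceMatrix"] = gldm_features(region, alpha=gldm_alpha)
    out["NeighbouringGrayToneDifferenceMatrix"] = ngtdm_features(region)
    return out


def extract_features(
    volume: SuvVolume,
    mask: np.ndarray,
    registry: FeatureRegistry | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    gldm_alpha: int = 0,
) -> pd.Series:
    """Compute the registry's feature vector for one patient.

    ``mask`` must be a boolean array on the volume grid with at least one
    voxel. Returns a Series indexed by the registry identifiers; every value
    is finite (degenerate regions produce the documented fallback 0).
    """
    registry = registry or default_registry()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {volume.shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")

    data, cmask = _crop_to_mask(volume.data, mask)
    vv = volume.voxel_volume()

    values: dict[str, float] = {}

    # original image: all intensity classes + shape + supplementary FO
    per_class = _class_features(data, cmask, bin_width, gldm_alpha, vv)
    for cls, feats in per_class.items():
        for name, val in feats.items():
            values[f"original_{cls}_{name}"] = val
    for name, val in shape_features(cmask, volume.spacing).items():
        values[f"original_Shape_{name}"] = val
    for name, val in first_order_extras(data[cmask], voxel_volume=vv).items():
        values[f"original_FirstOrder_{name}"] = val

    # wavelet sub-bands
    bank = wavelet_decompose(data)
    for band, sub in bank.items():
        per_class = _class_features(sub, cmask, bin_width, gldm_alpha, vv)
        for cls, feats in per_class.items():
            for name, val in feats.items():
                values[f"{band}_{cls}_{name}"] = val

    missing = [k for k in registry if k not in values]
    if missing:
        raise KeyError(
            f"registry identifiers not produced by extraction: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    vec = pd.Series({k: float(values[k]) for k in registry}, name="features")
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise FloatingPointError(f"non-finite feature values: {bad[:5]}")
    return vec
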