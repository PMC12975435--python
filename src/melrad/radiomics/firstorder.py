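"""First-order (histogram) intensity features."""

from __future__ import annotations

import numpy as np

from .discretize import DEFAULT_BIN_WIDTH, discretize

__all__ = ["first_order_features", "first_order_extras"]

_EPS = np.spacing(1.0)


def first_order_features(
    values, voxel_volume: float = 1.0, bin_width: float = DEFAULT_BIN_WIDTH
) -> dict[str, float]:
    """The 18 core first-order features of a flat intensity sample.

    Entropy and Uniformity use the fixed-bin-width discretization shared
    with the texture families; moments are population moments. Skewness and
    Kurtosis of a constant sample are defined as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    n = x.size
    mean = float(x.mean())
    var = float(x.var(ddof=0))
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    levels = discretize(x, bin_width)
    counts = np.bincount(levels)[1:]
    p = counts / n
    robust = x[(x >= p10) & (x <= p90)]
    m2 = var
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


def first_order_extras(values, voxel_volume: float = 1.0) -> dict[str, float]:
    """Supplementary first-order features reported on the original SUV image
    only. TotalLesionGlycolysis is mean SUV times lesion volume in cm^3."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    p25, p75 = np.percentile(x, [25, 75])
    return {
        "StandardDeviation": sd,
        "CoefficientOfVariation": sd / mean if mean != 0 else 0.0,
        "25Percentile": float(p25),
        "75Percentile": float(p75),
        "TotalLesionGlycolysis": mean * x.size * voxel_volume / 1000.0,
    }
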