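"""The feature registry: which features, on which image types, in which order.

The default registry pairs 93 intensity/texture features (18 first-order,
24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) with 9 image types (the
original SUV volume plus the 8 single-level coif1 stationary-wavelet
sub-bands), and adds 14 shape features and 5 supplementary first-order
features on the original image only:

    93 * 9 + 14 + 5 = 856 feature identifiers.

Identifiers read ``<image>_<Class>_<Name>``, e.g.
``HLL_GrayLevelCooccurrenceMatrix_ClusterProminence``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FeatureRegistry",
    "default_registry",
    "MELRAD_FEATURES",
    "IMAGE_TYPES",
    "FIRST_ORDER",
    "FIRST_ORDER_EXTRA",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "GLDM",
    "NGTDM",
    "SHAPE",
]

IMAGE_TYPES = (
    "original",
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)

FIRST_ORDER = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

#: Supplementary first-order features, computed on the original image only.
FIRST_ORDER_EXTRA = (
    "StandardDeviation", "CoefficientOfVariation", "25Percentile",
    "75Percentile", "TotalLesionGlycolysis",
)

GLCM = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)

GLRLM = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

SHAPE = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

CLASS_FEATURES = {
    "FirstOrder": FIRST_ORDER,
    "GrayLevelCooccurrenceMatrix": GLCM,
    "GrayLevelRunLengthMatrix": GLRLM,
    "GrayLevelSizeZoneMatrix": GLSZM,
    "GrayLevelDependenceMatrix": GLDM,
    "NeighbouringGrayToneDifferenceMatrix": NGTDM,
}

#: The three texture features retained by the MEL-RAD model.
MELRAD_FEATURES = (
    "LHH_GrayLevelRunLengthMatrix_GrayLevelVariance",
    "HLL_GrayLevelCooccurrenceMatrix_ClusterProminence",
    "HHH_GrayLevelDependenceMatrix_GrayLevelVariance",
)


@dataclass(frozen=True)
class FeatureRegistry:
    """An ordered, duplicate-free list of feature identifiers."""

    identifiers: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("registry identifiers must be unique")

    def __len__(self) -> int:
        return len(self.identifiers)

    def __iter__(self):
        return iter(self.identifiers)

    def index(self, identifier: str) -> int:
        return self.identifiers.index(identifier)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.identifiers) + "\n")

    @classmethod
    def from_file(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            ids = tuple(line.strip() for line in fh if line.strip())
        return cls(ids)


def default_registry() -> FeatureRegistry:
    """Build the default 856-identifier registry."""
    ids: list[str] = []
    for image in IMAGE_TYPES:
        for cls_name, feats in CLASS_FEATURES.items():
            ids.extend(f"{image}_{cls_name}_{name}" for name in feats)
    ids.extend(f"original_Shape_{name}" for name in SHAPE)
    ids.extend(f"original_FirstOrder_{name}" for name in FIRST_ORDER_EXTRA)
    return FeatureRegistry(tuple(ids))
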