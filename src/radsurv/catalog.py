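"""Radiomic feature catalog.

The standard CT radiomics panel produced by IBSI-conformant extractors:
14 shape descriptors, 18 first-order intensity statistics, and 75 texture
features (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM) computed on the
original image, plus copies of the 93 non-shape features computed on each
of the 8 wavelet-decomposition sub-bands — 744 wavelet features, 851 in
total.  Shape features are geometric and therefore have no wavelet
variants.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CatalogEntry",
    "FeatureCatalog",
    "build_feature_catalog",
    "WAVELET_SUB_BANDS",
]

SHAPE_FEATURES = (
    "Elongation",
    "Flatness",
    "LeastAxisLength",
    "MajorAxisLength",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "Maximum2DDiameterSlice",
    "Maximum3DDiameter",
    "MeshVolume",
    "MinorAxisLength",
    "Sphericity",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "VoxelVolume",
)

FIRSTORDER_FEATURES = (
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "MeanAbsoluteDeviation",
    "Mean",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
)

# Texture classes and their per-class feature names; counts 24+16+16+14+5 = 75.
TEXTURE_CLASSES = {
    "glcm": (
        "Autocorrelation",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointAverage",
        "JointEnergy",
        "JointEntropy",
        "MCC",
        "MaximumProbability",
        "SumAverage",
        "SumEntropy",
        "SumSquares",
    ),
    "glrlm": (
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelRunEmphasis",
        "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis",
        "RunEntropy",
        "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized",
        "RunPercentage",
        "RunVariance",
        "ShortRunEmphasis",
        "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelZoneEmphasis",
        "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis",
        "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized",
        "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy",
        "ZonePercentage",
        "ZoneVariance",
    ),
    "gldm": (
        "DependenceEntropy",
        "DependenceNonUniformity",
        "DependenceNonUniformityNormalized",
        "DependenceVariance",
        "GrayLevelNonUniformity",
        "GrayLevelVariance",
        "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "ngtdm": (
        "Busyness",
        "Coarseness",
        "Complexity",
        "Contrast",
        "Strength",
    ),
}

WAVELET_SUB_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

CATEGORIES = ("shape", "intensity", "texture", "wavelet")


@dataclass(frozen=True)
class CatalogEntry:
    """One feature: its column name, category, and wavelet sub-band (if any)."""

    name: str
    category: str  # shape | intensity | texture | wavelet
    sub_band: str = "none"  # none, or one of WAVELET_SUB_BANDS


class FeatureCatalog:
    """Ordered, deterministic catalog of the 851-feature radiomics panel."""

    def __init__(self, entries: list[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog feature names must be unique")
        self.entries = list(entries)
        self._names = names
        self._name_set = set(names)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._name_set

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self.entries:
            counts[e.category] += 1
        return counts

    def by_category(self, category: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.category == category]

    def by_sub_band(self, sub_band: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.sub_band == sub_band]


def build_feature_catalog() -> FeatureCatalog:
    """Construct the 851-entry catalog (14 shape / 18 intensity / 75 texture /
    744 wavelet).

    Names follow the ``<image>_<class>_<feature>`` convention of the common
    IBSI-conformant extractors, e.g. ``original_shape_SurfaceArea``,
    ``wavelet-HHH_glcm_Imc1``.  The wavelet block replicates the 93 non-shape
    features over the 8 sub-bands.
    """
    entries: list[CatalogEntry] = []
    for f in SHAPE_FEATURES:
        entries.append(CatalogEntry(f"original_shape_{f}", "shape"))
    for f in FIRSTORDER_FEATURES:
        entries.append(CatalogEntry(f"original_firstorder_{f}", "intensity"))
    for cls, feats in TEXTURE_CLASSES.items():
        for f in feats:
            entries.append(CatalogEntry(f"original_{cls}_{f}", "texture"))
    for band in WAVELET_SUB_BANDS:
        for f in FIRSTORDER_FEATURES:
            entries.append(
                CatalogEntry(f"wavelet-{band}_firstorder_{f}", "wavelet", band)
            )
        for cls, feats in TEXTURE_CLASSES.items():
            for f in feats:
                entries.append(
                    CatalogEntry(f"wavelet-{band}_{cls}_{f}", "wavelet", band)
                )
    return FeatureCatalog(entries)
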