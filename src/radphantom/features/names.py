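"""The 76-feature catalogue: 5 categories with fixed names and order.

Category sizes: 7 gradient-orientation-histogram, 22 GLCM, 11 gray-level
run-length, 31 intensity, 5 neighborhood gray-tone difference.  Column names
are ``<CategoryPrefix>_<FeatureName>`` so features that recur across
categories (Kurtosis, InterQuartileRange, Energy, Contrast, Variance) stay
distinct.
"""

from __future__ import annotations

GRADIENT_FEATURES = [
    "InterQuartileRange",
    "Kurtosis",
    "MeanAbsoluteDeviation",
    "MedianAbsoluteDeviation",
    "20PercentileArea",
    "50PercentileArea",
    "90PercentileArea",
]

GLCM_FEATURES = [
    "AutoCorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceEntropy",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity",
    "Homogeneity2",
    "InformationMeasureCorr1",
    "InformationMeasureCorr2",
    "InverseDiffMomentNorm",
    "InverseDiffNorm",
    "InverseVariance",
    "MaxProbability",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "Variance",
]

GLRL_FEATURES = [
    "GrayLevelNonuniformity",
    "HighGrayLevelRunEmpha",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmpha",
    "LongRunLowGrayLevelEmpha",
    "LowGrayLevelRunEmpha",
    "RunLengthNonuniformity",
    "RunPercentage",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmpha",
    "ShortRunLowGrayLevelEmpha",
]

INTENSITY_FEATURES = [
    "Energy",
    "EnergyNorm",
    "GlobalEntropy",
    "GlobalMean",
    "GlobalMedian",
    "GlobalStd",
    "GlobalUniformity",
    "InterQuartileRange",
    "Kurtosis",
    "LocalEntropyMax",
    "LocalEntropyMean",
    "LocalEntropyMedian",
    "LocalEntropyMin",
    "LocalEntropyStd",
    "LocalRangeMean",
    "LocalRangeMedian",
    "LocalRangeMin",
    "LocalRangeStd",
    "LocalStdMax",
    "LocalStdMean",
    "LocalStdMedian",
    "LocalStdMin",
    "LocalStdStd",
    "MeanAbsoluteDeviation",
    "MedianAbsoluteDeviation",
    "20Percentile",
    "50Percentile",
    "90Percentile",
    "RootMeanSquare",
    "Skewness",
    "Variance",
]

NGTD_FEATURES = [
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "TextureStrength",
]

CATEGORY_PREFIX = {
    "GradientOrientHistogram": "GradOriHist",
    "GLCM": "GLCM",
    "GLRL": "GLRL",
    "Intensity": "Intensity",
    "NGTD": "NGTD",
}

CATEGORY_FEATURES = {
    "GradientOrientHistogram": GRADIENT_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLRL": GLRL_FEATURES,
    "Intensity": INTENSITY_FEATURES,
    "NGTD": NGTD_FEATURES,
}

CATEGORY_SIZES = {cat: len(feats) for cat, feats in CATEGORY_FEATURES.items()}


def feature_columns() -> list[str]:
    """All 76 feature column names, in catalogue order."""
    cols = []
    for cat, feats in CATEGORY_FEATURES.items():
        prefix = CATEGORY_PREFIX[cat]
        cols.extend(f"{prefix}_{name}" for name in feats)
    return cols


ALL_FEATURES = feature_columns()
assert len(ALL_FEATURES) == 76
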