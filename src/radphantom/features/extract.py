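"""End-to-end feature extraction: preprocessing arm -> matrices -> 76 features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..image import ImageVolume, ROIMask
from ..preprocess import butterworth_smooth, normalize_3sigma, quantize_gray_levels
from .glcm import DEFAULT_OFFSETS_2D, compute_glcm, glcm_features
from .glrlm import DEFAULT_DIRECTIONS_2D, compute_glrlm, glrl_features
from .gradient import gradient_histogram_features
from .intensity import intensity_features
from .names import ALL_FEATURES, CATEGORY_FEATURES, CATEGORY_PREFIX
from .ngtdm import ngtd_features

__all__ = ["FeatureConfig", "FeatureVector", "extract_all_features"]


@dataclass(frozen=True)
class FeatureConfig:
    """Preprocessing arm and extractor settings.

    ``normalize`` and ``smooth`` are the two optional preprocessing switches;
    with both off the raw intensities are analyzed.  ``n_levels`` is the
    gray-level quantization used by all texture matrices and histogram
    statistics.
    """

    normalize: bool = False
    smooth: bool = False
    smooth_cutoff: float = 0.25  # cycles/voxel
    smooth_order: int = 2
    n_levels: int = 64
    local_window: int = 3
    glcm_offsets: tuple = DEFAULT_OFFSETS_2D
    glrl_directions: tuple = DEFAULT_DIRECTIONS_2D

    @property
    def arm(self) -> str:
        if self.normalize and self.smooth:
            return "normalized+filtered"
        if self.normalize:
            return "normalized"
        if self.smooth:
            return "filtered"
        return "none"


@dataclass
class FeatureVector:
    """The 76 named feature values of one ROI plus extraction provenance."""

    values: dict[str, float]
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values) != ALL_FEATURES:
            missing = set(ALL_FEATURES) - set(self.values)
            extra = set(self.values) - set(ALL_FEATURES)
            raise ValueError(f"feature set mismatch; missing={missing} extra={extra}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def by_category(self) -> dict[str, dict[str, float]]:
        out = {}
        for cat, feats in CATEGORY_FEATURES.items():
            prefix = CATEGORY_PREFIX[cat]
            out[cat] = {f: self.values[f"{prefix}_{f}"] for f in feats}
        return out


def _crop_to_roi(
    image: ImageVolume, mask: ROIMask, pad: int = 2
) -> tuple[ImageVolume, ROIMask]:
    """Crop both volumes to the ROI bounding box (padded) to bound the work."""
    idx = np.nonzero(mask.mask)
    sl = tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, s))
        for i, s in zip(idx, mask.shape)
    )
    sub = ImageVolume(
        image.data[sl],
        image.spacing,
        tuple(
            image.origin[a] + image.spacing[a] * sl[a].start for a in range(3)
        ),
    )
    return sub, ROIMask(mask.mask[sl], mask.label, sub.spacing, sub.origin)


def extract_all_features(
    image: ImageVolume, mask: ROIMask, config: FeatureConfig | None = None
) -> FeatureVector:
    """Run the preprocessing arm and compute all 76 features for one ROI.

    The quantization is computed once and shared by the texture matrices and
    histogram statistics, so all categories see the same gray levels.
    """
    if config is None:
        config = FeatureConfig()
    if mask.is_empty():
        raise ValueError("mask is empty")
    image, mask = _crop_to_roi(image, mask)
    if config.smooth:
        image = butterworth_smooth(image, config.smooth_cutoff, config.smooth_order)
    if config.normalize:
        image = normalize_3sigma(image, mask)

    q = quantize_gray_levels(image, mask, config.n_levels)

    values: dict[str, float] = {}

    def _add(category: str, feats: dict[str, float]) -> None:
        prefix = CATEGORY_PREFIX[category]
        for name in CATEGORY_FEATURES[category]:
            try:
                values[f"{prefix}_{name}"] = float(feats[name])
            except KeyError:  # pragma: no cover - catalogue/implementation drift
                raise RuntimeError(f"{category} did not produce feature {name!r}")

    try:
        _add("GradientOrientHistogram", gradient_histogram_features(image, mask))
    except ValueError as err:
        raise ValueError(f"gradient-orientation features failed: {err}") from err
    try:
        glcm = compute_glcm(q, offsets=config.glcm_offsets)
        _add("GLCM", glcm_features(glcm))
    except ValueError as err:
        raise ValueError(f"GLCM features failed: {err}") from err
    try:
        glrlm = compute_glrlm(q, directions=config.glrl_directions)
        _add("GLRL", glrl_features(glrlm))
    except ValueError as err:
        raise ValueError(f"GLRL features failed: {err}") from err
    _add("Intensity", intensity_features(image, mask, q, config.local_window))
    try:
        _add("NGTD", ngtd_features(q))
    except ValueError as err:
        raise ValueError(f"NGTD features failed: {err}") from err

    ordered = {name: values[name] for name in ALL_FEATURES}
    provenance = {
        "arm": config.arm,
        "n_levels": config.n_levels,
        "local_window": config.local_window,
        "glcm_offsets": config.glcm_offsets,
        "roi_label": mask.label,
        "roi_voxels": mask.count(),
    }
    return FeatureVector(ordered, provenance)
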