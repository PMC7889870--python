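"""Optional intensity normalization, Butterworth smoothing, and gray-level quantization.

The analysis pipeline has four preprocessing arms: raw intensities,
3-sigma normalization, Butterworth low-pass smoothing, and (for ROI-size
comparisons) a smaller ROI on raw intensities.  Quantization is not an arm:
it is always applied inside the texture-matrix builders, which operate on
small integer gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageVolume, ROIMask

__all__ = [
    "QuantizedROI",
    "normalize_3sigma",
    "butterworth_smooth",
    "quantize_gray_levels",
]


@dataclass
class QuantizedROI:
    """Integer gray levels (1..n_levels) for the voxels of one ROI.

    ``levels`` is a full-size integer array with 0 outside the mask, which
    keeps neighborhood bookkeeping (offsets, runs, mask boundaries) simple.
    """

    levels: np.ndarray  # int array, 0 = outside mask
    mask: np.ndarray  # boolean
    n_levels: int
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("quantized ROI is empty")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("levels out of range 1..n_levels")

    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def normalize_3sigma(image: ImageVolume, mask: ROIMask) -> ImageVolume:
    """Map in-ROI intensities onto [0, 1] by centering the +/-3 sigma band.

    x -> (x - mu + 3 sigma) / (6 sigma), clipped to [0, 1], with mu and sigma
    the in-mask mean and SD.  The mean maps to 0.5 and values beyond three
    SDs saturate.  The mapping is invariant under positive affine changes of
    the input intensities, which is what makes it useful across scanners.
    Voxels outside the mask are left untouched.
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    vals = image.data[mask.mask]
    mu = vals.mean()
    sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sigma == 0:
        raise ValueError("in-mask SD is zero; 3-sigma normalization undefined")
    out = image.data.copy()
    out[mask.mask] = np.clip((vals - mu + 3.0 * sigma) / (6.0 * sigma), 0.0, 1.0)
    return image.copy_with(out)


def butterworth_smooth(
    image: ImageVolume, cutoff: float = 0.25, order: int = 2
) -> ImageVolume:
    """Frequency-domain Butterworth low-pass smoothing in 3D.

    Gain ``1 / (1 + (f / cutoff)^(2 order))`` with f the radial spatial
    frequency in cycles/voxel; the DC gain is exactly 1, so the mean
    intensity is preserved.  Butterworth filters are maximally flat in the
    passband, which is why they are favored as "edge-preserving" smoothers:
    structure below the cutoff passes nearly untouched while high-frequency
    noise is rolled off monotonically.
    """
    if not 0 < cutoff <= 0.5:
        raise ValueError("cutoff must be in (0, 0.5] cycles/voxel")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not np.isfinite(image.data).all():
        raise ValueError("image contains non-finite voxels")
    freqs = [np.fft.fftfreq(n) for n in image.shape]
    f2 = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    gain = 1.0 / (1.0 + (f2 / cutoff**2) ** order)
    smoothed = np.fft.ifftn(np.fft.fftn(image.data) * gain).real
    return image.copy_with(smoothed)


def quantize_gray_levels(
    image: ImageVolume, mask: ROIMask, n_levels: int = 64
) -> QuantizedROI:
    """Quantize in-ROI intensities into equal-width bins over [min, max].

    The in-mask minimum maps to level 1 and the maximum to ``n_levels``
    (the top edge is closed).  A constant ROI maps to a single level 1.
    Quantization is monotone in the input intensities.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if mask.is_empty():
        raise ValueError("mask is empty")
    vals = image.data[mask.mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.mask] = 1
    else:
        scaled = (image.data[mask.mask] - vmin) / (vmax - vmin) * n_levels
        levels[mask.mask] = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_levels)
    return QuantizedROI(levels, mask.mask.copy(), int(n_levels), vmin, vmax)
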