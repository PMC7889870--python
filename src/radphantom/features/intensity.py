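"""First-order intensity statistics: 31 global and local-map features.

Global statistics are computed on the raw in-ROI intensities; the histogram
statistics (GlobalEntropy, GlobalUniformity) use the ROI's gray-level
quantization.  Local maps (entropy, range, SD) are computed per axial slice
over a 3x3 in-plane window restricted to in-mask voxels, then summarized
across the ROI.

Conventions: variance-style statistics use the sample (n-1) denominator;
percentiles use linear interpolation; skewness and kurtosis use population
moment ratios (kurtosis is the non-excess Pearson form, 3 for a normal);
degenerate (zero-variance) skewness and kurtosis are reported as 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from ..image import ImageVolume, ROIMask
from ..preprocess import QuantizedROI, quantize_gray_levels

__all__ = ["intensity_features"]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _local_maps(
    image: np.ndarray, mask: np.ndarray, q: QuantizedROI, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel local entropy / range / sample SD over a 2D window, in-mask only."""
    kernel = np.ones((window, window))
    ent_vals, rng_vals, std_vals = [], [], []
    big = np.finfo(float).max / 4
    for k in range(image.shape[2]):
        msk = mask[:, :, k]
        if not msk.any():
            continue
        sl = np.where(msk, image[:, :, k], 0.0)
        cnt = ndimage.correlate(msk.astype(float), kernel, mode="constant", cval=0.0)
        s1 = ndimage.correlate(sl, kernel, mode="constant", cval=0.0)
        s2 = ndimage.correlate(sl**2, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (s2 - s1**2 / cnt) / (cnt - 1.0)
        var = np.where(cnt > 1, np.maximum(var, 0.0), 0.0)
        mx = ndimage.maximum_filter(
            np.where(msk, image[:, :, k], -big), size=window, mode="constant", cval=-big
        )
        mn = ndimage.minimum_filter(
            np.where(msk, image[:, :, k], big), size=window, mode="constant", cval=big
        )
        ent = np.zeros_like(sl)
        lv = q.levels[:, :, k]
        for level in np.unique(lv[msk]):
            c = ndimage.correlate(
                ((lv == level) & msk).astype(float), kernel, mode="constant", cval=0.0
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                p = c / cnt
            ent -= np.where(c > 0, _xlog2(np.where(p > 0, p, 1.0)), 0.0)
        ent_vals.append(ent[msk])
        rng_vals.append((mx - mn)[msk])
        std_vals.append(np.sqrt(var)[msk])
    return (np.concatenate(ent_vals), np.concatenate(rng_vals), np.concatenate(std_vals))


def intensity_features(
    image: ImageVolume,
    mask: ROIMask,
    q: QuantizedROI | None = None,
    local_window: int = 3,
) -> dict[str, float]:
    """The 31 intensity statistics for one ROI.

    ``q`` supplies the gray-level quantization used by the histogram and
    local-entropy statistics; when omitted it is computed with the default
    64 levels.
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    if q is None:
        q = quantize_gray_levels(image, mask)
    x = image.data[mask.mask]
    n = x.size
    mean = float(x.mean())
    median = float(np.median(x))
    std = float(x.std(ddof=1)) if n > 1 else 0.0
    var = std**2
    hist = np.bincount(q.in_mask_levels(), minlength=q.n_levels + 1)[1:]
    p = hist / hist.sum()
    entropy = float(-_xlog2(p).sum())
    uniformity = float((p**2).sum())
    if std > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    q25, q75 = np.percentile(x, [25, 75])
    local_ent, local_rng, local_std = _local_maps(
        image.data, mask.mask, q, local_window
    )

    def _summ(vals: np.ndarray, stat: str) -> float:
        if stat == "Max":
            return float(vals.max())
        if stat == "Mean":
            return float(vals.mean())
        if stat == "Median":
            return float(np.median(vals))
        if stat == "Min":
            return float(vals.min())
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0  # Std

    out = {
        "Energy": float((x**2).sum()),
        "EnergyNorm": float((x**2).sum() / n),
        "GlobalEntropy": entropy,
        "GlobalMean": mean,
        "GlobalMedian": median,
        "GlobalStd": std,
        "GlobalUniformity": uniformity,
        "InterQuartileRange": float(q75 - q25),
        "Kurtosis": kurt,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "MedianAbsoluteDeviation": float(np.median(np.abs(x - median))),
        "20Percentile": float(np.percentile(x, 20)),
        "50Percentile": float(np.percentile(x, 50)),
        "90Percentile": float(np.percentile(x, 90)),
        "RootMeanSquare": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Variance": var,
    }
    for stat in ("Max", "Mean", "Median", "Min", "Std"):
        out[f"LocalEntropy{stat}"] = _summ(local_ent, stat)
    for stat in ("Mean", "Median", "Min", "Std"):
        out[f"LocalRange{stat}"] = _summ(local_rng, stat)
    for stat in ("Max", "Mean", "Median", "Min", "Std"):
        out[f"LocalStd{stat}"] = _summ(local_std, stat)
    return out
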