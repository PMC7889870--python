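"""Gray-level co-occurrence matrix and the 22 Haralick-family statistics.

The matrix is accumulated per axial slice in 2D over the four unit offsets
(0, 45, 90 and 135 degrees at distance 1 by default), summed across slices
into a single matrix per ROI, symmetrized and normalized to probabilities.
Voxel pairs are counted only when both voxels are inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import QuantizedROI

__all__ = ["GLCMatrix", "compute_glcm", "glcm_features", "DEFAULT_OFFSETS_2D"]

#: in-plane (dx, dy) unit displacements: 0, 45, 90, 135 degrees
DEFAULT_OFFSETS_2D: tuple[tuple[int, int], ...] = ((1, 0), (1, 1), (0, 1), (-1, 1))

_EPS = np.finfo(float).tiny


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities P (n_levels x n_levels)."""

    P: np.ndarray
    offsets: tuple
    symmetric: bool

    def __post_init__(self) -> None:
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if (self.P < 0).any():
            raise ValueError("P has negative entries")
        if not np.isclose(self.P.sum(), 1.0):
            raise ValueError("P must sum to 1")

    @property
    def n_levels(self) -> int:
        return self.P.shape[0]

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.P.sum(axis=1), self.P.sum(axis=0)


def compute_glcm(
    q: QuantizedROI,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS_2D,
    symmetric: bool = True,
) -> GLCMatrix:
    """Accumulate co-occurrence counts over all offsets and axial slices.

    Offsets are (dx, dy) displacements applied within each z-slice.  With
    ``symmetric`` each ordered pair is counted in both directions, making P
    symmetric by construction.
    """
    if not offsets:
        raise ValueError("offset list is empty")
    n = q.n_levels
    counts = np.zeros((n, n), dtype=np.float64)
    lev = q.levels  # 0 outside mask
    for dx, dy in offsets:
        a, b = _shifted_pairs(lev, dx, dy)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid voxel pairs for any offset")
    return GLCMatrix(counts / total, tuple(offsets), symmetric)


def _shifted_pairs(lev: np.ndarray, dx: int, dy: int) -> tuple[np.ndarray, np.ndarray]:
    """Level arrays of (voxel, neighbor-at-offset) pairs within array bounds."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    for axis, d in ((0, dx), (1, dy)):
        if d > 0:
            sl_a[axis] = slice(0, -d)
            sl_b[axis] = slice(d, None)
        elif d < 0:
            sl_a[axis] = slice(-d, None)
            sl_b[axis] = slice(0, d)
    return lev[tuple(sl_a)].ravel(), lev[tuple(sl_b)].ravel()


def glcm_features(M: GLCMatrix) -> dict[str, float]:
    """The 22 co-occurrence statistics.

    Entropies use log base 2.  Degenerate rules: Correlation and the two
    information measures of correlation return 0 when a marginal is
    degenerate (zero SD / zero entropy); InformationMeasureCorr2's radicand
    is clamped at 0.
    """
    P = M.P
    n = M.n_levels
    i = np.arange(1, n + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px, py = M.marginals()
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal / cross-diagonal marginals p_{x+y}(k), k = 2..2n, and p_{x-y}(k), k = 0..n-1
    ksum = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.array([P[(I + J) == k].sum() for k in ksum])
    kdiff = np.arange(0, n, dtype=float)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in kdiff])

    autocorr = float((I * J * P).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    dissim = float((np.abs(I - J) * P).sum())
    energy = float((P**2).sum())
    entropy = float(-_xlog2(P).sum())
    homog = float((P / (1.0 + np.abs(I - J))).sum())
    homog2 = float((P / (1.0 + (I - J) ** 2)).sum())
    idmn = float((P / (1.0 + ((I - J) / n) ** 2)).sum())
    idn = float((P / (1.0 + np.abs(I - J) / n)).sum())
    off_diag = I != J
    inv_var = float((P[off_diag] / (I[off_diag] - J[off_diag]) ** 2).sum())
    maxprob = float(P.max())
    sum_avg = float((ksum * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    sum_var = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    diff_entropy = float(-_xlog2(p_diff).sum())
    cluster = I + J - mu_x - mu_y
    cl_tend = float((cluster**2 * P).sum())
    cl_shade = float((cluster**3 * P).sum())
    cl_prom = float((cluster**4 * P).sum())
    variance = float(((I - mu_x) ** 2 * P).sum())

    if sig_x > 0 and sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.maximum(pxpy, _EPS)), 0.0)
    hxy1 = float(-(P * log_pxpy).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    if max(hx, hy) > 0:
        imc1 = (entropy - hxy1) / max(hx, hy)
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    else:
        imc1 = 0.0
        imc2 = 0.0

    return {
        "AutoCorrelation": autocorr,
        "ClusterProminence": cl_prom,
        "ClusterShade": cl_shade,
        "ClusterTendency": cl_tend,
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceEntropy": diff_entropy,
        "Dissimilarity": dissim,
        "Energy": energy,
        "Entropy": entropy,
        "Homogeneity": homog,
        "Homogeneity2": homog2,
        "InformationMeasureCorr1": float(imc1),
        "InformationMeasureCorr2": imc2,
        "InverseDiffMomentNorm": idmn,
        "InverseDiffNorm": idn,
        "InverseVariance": inv_var,
        "MaxProbability": maxprob,
        "SumAverage": sum_avg,
        "SumEntropy": sum_entropy,
        "SumVariance": sum_var,
        "Variance": variance,
    }
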