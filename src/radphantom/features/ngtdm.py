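"""Neighborhood gray-tone difference table and the five Amadasun-King statistics.

For every voxel whose complete 2D 8-neighborhood lies inside the mask (and
inside the slice), the absolute difference between the voxel's gray level
and the mean level of its 8 neighbors is accumulated per level.  The five
statistics - coarseness, contrast, busyness, complexity, texture strength -
summarize how rapidly and how strongly gray tone changes across the region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import QuantizedROI

__all__ = ["NGTDTable", "compute_ngtd_table", "ngtd_features", "NGTD_EPS"]

#: cap / regularizer for the reciprocal statistics on homogeneous regions
NGTD_EPS = 1e-6


@dataclass
class NGTDTable:
    """Per-level occupancy p_i, summed neighborhood difference s_i, counts n_i."""

    p: np.ndarray  # occupancy probability per level, length n_levels
    s: np.ndarray  # summed |level - neighborhood mean| per level
    counts: np.ndarray
    n_valid: int

    def __post_init__(self) -> None:
        if self.n_valid <= 0:
            raise ValueError("no valid voxels with a complete in-mask neighborhood")
        if (self.s < 0).any():
            raise ValueError("s_i must be >= 0")


def compute_ngtd_table(q: QuantizedROI) -> NGTDTable:
    """Accumulate the gray-tone difference table over all axial slices."""
    lev = q.levels.astype(np.float64)
    mask = q.mask
    n = q.n_levels
    counts = np.zeros(n)
    s = np.zeros(n)
    n_valid = 0
    for k in range(lev.shape[2]):
        sl = lev[:, :, k]
        msk = mask[:, :, k]
        if not msk.any():
            continue
        # complete 8-neighborhood inside the mask: 3x3 erosion, excluding edges
        core = np.zeros_like(msk)
        core[1:-1, 1:-1] = (
            msk[:-2, :-2] & msk[:-2, 1:-1] & msk[:-2, 2:]
            & msk[1:-1, :-2] & msk[1:-1, 1:-1] & msk[1:-1, 2:]
            & msk[2:, :-2] & msk[2:, 1:-1] & msk[2:, 2:]
        )
        if not core.any():
            continue
        nb_sum = (
            sl[:-2, :-2] + sl[:-2, 1:-1] + sl[:-2, 2:]
            + sl[1:-1, :-2] + sl[1:-1, 2:]
            + sl[2:, :-2] + sl[2:, 1:-1] + sl[2:, 2:]
        )
        nb_mean = np.zeros_like(sl)
        nb_mean[1:-1, 1:-1] = nb_sum / 8.0
        valid = core
        vl = sl[valid].astype(int)
        diffs = np.abs(sl[valid] - nb_mean[valid])
        np.add.at(counts, vl - 1, 1.0)
        np.add.at(s, vl - 1, diffs)
        n_valid += int(valid.sum())
    if n_valid == 0:
        raise ValueError("no voxel has a complete in-mask 8-neighborhood")
    return NGTDTable(p=counts / n_valid, s=s, counts=counts, n_valid=n_valid)


def ngtd_features(q: QuantizedROI) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and texture strength.

    Degenerate rules for perfectly homogeneous regions: Coarseness is
    regularized as ``1 / (eps + sum p_i s_i)`` and therefore capped at
    ``1/eps``; Contrast is 0 when fewer than two levels occur; Busyness is 0
    when its denominator vanishes.
    """
    table = compute_ngtd_table(q)
    p, s, n = table.p, table.s, table.n_valid
    present = p > 0
    levels = np.arange(1, len(p) + 1, dtype=float)
    n_g = int(present.sum())

    coarseness = 1.0 / (NGTD_EPS + float((p * s).sum()))

    if n_g >= 2:
        pi = p[present]
        li = levels[present]
        dif2 = (li[:, None] - li[None, :]) ** 2
        contrast = (
            float((pi[:, None] * pi[None, :] * dif2).sum()) / (n_g * (n_g - 1))
        ) * (float(s.sum()) / n)
    else:
        contrast = 0.0

    ipi = levels[present] * p[present]
    busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
    busyness = float((p * s).sum()) / busy_den if busy_den > 0 else 0.0

    complexity = 0.0
    strength = 0.0
    if n_g >= 1:
        pi = p[present]
        si = s[present]
        li = levels[present]
        dif = np.abs(li[:, None] - li[None, :])
        psum = pi[:, None] + pi[None, :]
        num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        complexity = float((dif * num / psum).sum()) / n
        strength = float((psum * (li[:, None] - li[None, :]) ** 2).sum()) / (
            NGTD_EPS + float(s.sum())
        )

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "TextureStrength": strength,
    }
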