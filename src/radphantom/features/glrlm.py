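"""Gray-level run-length matrix and the 11 Galloway-family statistics.

Runs are maximal stretches of identical gray level along a scan direction,
broken at mask boundaries.  Matrices are built per axial slice over the four
2D directions (horizontal, vertical, both diagonals) and summed across
slices and directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess import QuantizedROI

__all__ = ["GLRLMatrix", "compute_glrlm", "glrl_features", "DEFAULT_DIRECTIONS_2D"]

DEFAULT_DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1), (1, -1))


@dataclass
class GLRLMatrix:
    """Run counts r[i, l]: gray level i (rows, 1-based) by run length l (cols, 1-based)."""

    r: np.ndarray
    n_voxels_traversed: int  # sum over directions of in-mask voxels scanned

    def __post_init__(self) -> None:
        if (self.r < 0).any():
            raise ValueError("negative run counts")

    @property
    def n_runs(self) -> float:
        return float(self.r.sum())

    def length_weighted_total(self) -> float:
        lengths = np.arange(1, self.r.shape[1] + 1, dtype=float)
        return float((self.r * lengths[None, :]).sum())


def _run_length_encode_lines(lines: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RLE of a stack of lines flattened with 0-separators; returns (levels, lengths)."""
    # append a separator column so runs never bridge lines
    sep = np.zeros((lines.shape[0], 1), dtype=lines.dtype)
    flat = np.concatenate([lines, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    levels = flat[starts]
    keep = levels > 0
    return levels[keep], (ends - starts)[keep]


def _diagonal_lines(sl: np.ndarray, anti: bool) -> np.ndarray:
    """Shear a 2D slice so its (anti)diagonals become rows, padded with 0."""
    h, w = sl.shape
    out = np.zeros((h, w + h - 1), dtype=sl.dtype)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    # column j - i is constant along main diagonals, j + i along antidiagonals
    shift = np.arange(h) if anti else (h - 1 - np.arange(h))
    out[rows, cols + shift[:, None]] = sl
    # after shearing, runs along the diagonal lie along columns
    return out.T


def compute_glrlm(
    q: QuantizedROI,
    directions: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS_2D,
) -> GLRLMatrix:
    """Count maximal same-level runs per direction within the mask.

    Directions are in-plane (dx, dy) steps; out-of-mask voxels (level 0)
    terminate runs, so runs never cross the mask boundary.
    """
    if not directions:
        raise ValueError("direction list is empty")
    n = q.n_levels
    max_len = max(q.levels.shape)
    counts = np.zeros((n, max_len), dtype=np.float64)
    lev = q.levels
    n_inmask = int(q.mask.sum())
    for dx, dy in directions:
        if (dx, dy) not in ((1, 0), (0, 1), (1, 1), (1, -1)):
            raise ValueError(f"unsupported 2D direction {(dx, dy)}")
        for k in range(lev.shape[2]):
            sl = lev[:, :, k]
            if dx == 1 and dy == 0:
                lines = sl.T  # runs along axis 0 -> lines are columns
            elif dx == 0 and dy == 1:
                lines = sl
            else:
                lines = _diagonal_lines(sl, anti=(dy == -1))
            levels, lengths = _run_length_encode_lines(np.ascontiguousarray(lines))
            if levels.size:
                np.add.at(counts, (levels - 1, lengths - 1), 1.0)
    if counts.sum() == 0:
        raise ValueError("no runs found (empty mask?)")
    return GLRLMatrix(counts, n_voxels_traversed=n_inmask * len(directions))


def glrl_features(R: GLRLMatrix) -> dict[str, float]:
    """The 11 run-length statistics.

    RunPercentage is the number of runs divided by the number of voxels
    traversed (the length-weighted run total), so a fully fragmented region
    scores 1 and long runs pull it toward 0.
    """
    r = R.r
    n_runs = R.n_runs
    if n_runs == 0:
        raise ValueError("matrix has no runs")
    n_lev, n_len = r.shape
    i = np.arange(1, n_lev + 1, dtype=float)[:, None]
    l = np.arange(1, n_len + 1, dtype=float)[None, :]
    by_level = r.sum(axis=1)
    by_length = r.sum(axis=0)
    traversed = R.length_weighted_total()
    return {
        "GrayLevelNonuniformity": float((by_level**2).sum() / n_runs),
        "HighGrayLevelRunEmpha": float((r * i**2).sum() / n_runs),
        "LongRunEmphasis": float((r * l**2).sum() / n_runs),
        "LongRunHighGrayLevelEmpha": float((r * i**2 * l**2).sum() / n_runs),
        "LongRunLowGrayLevelEmpha": float((r * l**2 / i**2).sum() / n_runs),
        "LowGrayLevelRunEmpha": float((r / i**2).sum() / n_runs),
        "RunLengthNonuniformity": float((by_length**2).sum() / n_runs),
        "RunPercentage": float(n_runs / traversed),
        "ShortRunEmphasis": float((r / l**2).sum() / n_runs),
        "ShortRunHighGrayLevelEmpha": float((r * i**2 / l**2).sum() / n_runs),
        "ShortRunLowGrayLevelEmpha": float((r / (i**2 * l**2)).sum() / n_runs),
    }
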