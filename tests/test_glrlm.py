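"""Run-length matrix: hand examples, brute-force run scanning, conservation."""

import numpy as np
import pytest

from radphantom.features.glrlm import (
    DEFAULT_DIRECTIONS_2D,
    GLRLMatrix,
    compute_glrlm,
    glrl_features,
)

from .conftest import make_quantized


def brute_force_runs(levels_2d, direction):
    """Oracle: walk every scan line in `direction`, collecting maximal runs."""
    lev = np.asarray(levels_2d)
    h, w = lev.shape
    dx, dy = direction
    # starting points: cells with no predecessor along the direction
    runs = []
    for x0 in range(h):
        for y0 in range(w):
            px, py = x0 - dx, y0 - dy
            if 0 <= px < h and 0 <= py < w:
                continue
            line = []
            x, y = x0, y0
            while 0 <= x < h and 0 <= y < w:
                line.append(lev[x, y])
                x, y = x + dx, y + dy
            current, length = None, 0
            for v in line + [0]:
                if v == current and v != 0:
                    length += 1
                else:
                    if current not in (None, 0) and length:
                        runs.append((current, length))
                    current, length = v, 1
    return runs


def runs_to_matrix(runs, n_levels, max_len):
    r = np.zeros((n_levels, max_len))
    for level, length in runs:
        r[level - 1, length - 1] += 1
    return r


class TestComputeGLRLM:
    def test_row_hand_example(self):
        # [1,1,2,2,2] horizontally: one run of 1s (len 2), one of 2s (len 3)
        q = make_quantized([[1, 1, 2, 2, 2]])
        R = compute_glrlm(q, directions=((0, 1),))
        assert R.r[0, 1] == 1  # level 1, length 2
        assert R.r[1, 2] == 1  # level 2, length 3
        assert R.n_runs == 2
        assert R.length_weighted_total() == 5

    def test_constant_row_single_run(self):
        q = make_quantized([[1, 1, 1, 1, 1]], n_levels=2)
        R = compute_glrlm(q, directions=((0, 1),))
        assert R.r[0, 4] == 1
        assert R.n_runs == 1

    def test_mask_boundary_breaks_runs(self):
        lev = np.array([[1, 0, 1, 1]], dtype=np.int32)[:, :, None]
        q = make_quantized(lev, n_levels=1)
        R = compute_glrlm(q, directions=((0, 1),))
        assert R.r[0, 0] == 1 and R.r[0, 1] == 1  # runs of length 1 and 2

    def test_empty_direction_list_raises(self):
        q = make_quantized([[1, 2]])
        with pytest.raises(ValueError, match="direction"):
            compute_glrlm(q, directions=())

    @pytest.mark.parametrize("direction", DEFAULT_DIRECTIONS_2D)
    def test_oracle_equivalence_random_slices(self, rng, direction):
        """Each direction's matrix equals explicit line walking on 60 random slices."""
        for _ in range(60):
            n_levels = int(rng.integers(2, 6))
            h, w = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            lev2d = rng.integers(1, n_levels + 1, size=(h, w))
            q = make_quantized(lev2d[:, :, None].astype(np.int32), n_levels=n_levels)
            R = compute_glrlm(q, directions=(direction,))
            expected = runs_to_matrix(
                brute_force_runs(lev2d, direction), n_levels, R.r.shape[1]
            )
            np.testing.assert_array_equal(R.r, expected)

    def test_voxel_conservation_per_direction(self, rng):
        """Sum of l * r(i, l) equals the in-mask voxel count for every direction."""
        lev = rng.integers(1, 5, size=(7, 6, 3)).astype(np.int32)
        mask = rng.random((7, 6, 3)) > 0.3
        lev = np.where(mask, lev, 0)
        if not mask.any():
            mask[0, 0, 0] = True
            lev[0, 0, 0] = 1
        q = make_quantized(lev, n_levels=4, mask=mask)
        for direction in DEFAULT_DIRECTIONS_2D:
            R = compute_glrlm(q, directions=(direction,))
            assert R.length_weighted_total() == mask.sum()


class TestGLRLFeatures:
    def test_hand_example_two_runs(self):
        r = np.zeros((2, 3))
        r[0, 1] = 1  # level 1, length 2
        r[1, 2] = 1  # level 2, length 3
        f = glrl_features(GLRLMatrix(r, n_voxels_traversed=5))
        assert f["ShortRunEmphasis"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["LongRunEmphasis"] == pytest.approx(6.5)
        assert f["RunPercentage"] == pytest.approx(0.4)

    def test_all_length_one_runs(self):
        r = np.zeros((3, 2))
        r[0, 0] = 2
        r[2, 0] = 3
        f = glrl_features(GLRLMatrix(r, n_voxels_traversed=5))
        assert f["ShortRunEmphasis"] == 1.0
        assert f["LongRunEmphasis"] == 1.0
        assert f["RunPercentage"] == 1.0

    def test_gray_level_nonuniformity_hand(self):
        r = np.zeros((2, 3))
        r[0, 0] = 1
        r[0, 2] = 1  # two runs, both gray level 1
        f = glrl_features(GLRLMatrix(r, n_voxels_traversed=4))
        assert f["GrayLevelNonuniformity"] == pytest.approx(2.0)

    def test_feature_count(self, rng):
        r = rng.integers(0, 5, size=(4, 6)).astype(float)
        r[0, 0] += 1
        f = glrl_features(GLRLMatrix(r, n_voxels_traversed=100))
        assert len(f) == 11
        assert all(np.isfinite(v) for v in f.values())
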