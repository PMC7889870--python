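"""COV, ICC(1,1), categorization, suitability, group averages, heat map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radphantom.phantom import synth_population_bounds
from radphantom.robustness import (
    categorize_cov,
    categorize_icc,
    cov_percent,
    group_average_cov,
    heatmap_matrix,
    icc_1_1,
    suitability_percent,
)


class TestCov:
    def test_constant_values_zero_cov(self):
        assert cov_percent([10, 10, 10]).cov_percent == 0.0

    def test_hand_arithmetic(self):
        r = cov_percent([8, 10, 12])
        assert r.sigma == pytest.approx(2.0)
        assert r.mu == pytest.approx(10.0)
        assert r.cov_percent == pytest.approx(20.0, abs=1e-9)

    def test_scale_invariance(self):
        assert cov_percent([16, 20, 24]).cov_percent == pytest.approx(20.0, abs=1e-9)

    def test_not_shift_invariant(self):
        a = cov_percent([8, 10, 12]).cov_percent
        b = cov_percent([108, 110, 112]).cov_percent
        assert a != pytest.approx(b)

    def test_negative_mean_uses_magnitude(self):
        r = cov_percent([-8, -10, -12])
        assert r.cov_percent == pytest.approx(20.0, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="mean is zero"):
            cov_percent([-1.0, 1.0])
        with pytest.raises(ValueError, match="at least 2"):
            cov_percent([5.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        vals=st.lists(st.floats(1.0, 1e6), min_size=2, max_size=12),
        c=st.floats(0.01, 100.0),
    )
    def test_positive_scaling_property(self, vals, c):
        a = cov_percent(vals).cov_percent
        b = cov_percent([c * v for v in vals]).cov_percent
        assert b == pytest.approx(a, rel=1e-9, abs=1e-9)


class TestCategorizeCov:
    @pytest.mark.parametrize(
        "cov,expected",
        [
            (6.05, "small"),
            (10.0, "small"),
            (10.01, "intermediate"),
            (30.0, "intermediate"),
            (30.01, "large"),
            (45.49, "large"),
            (0.0, "small"),
        ],
    )
    def test_boundaries(self, cov, expected):
        assert categorize_cov(cov) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_cov(-0.1)


class TestIcc:
    def test_perfect_agreement(self):
        assert icc_1_1([[1, 1], [2, 2], [3, 3]]).icc == pytest.approx(1.0)

    def test_hand_anova(self):
        r = icc_1_1([[1, 2], [3, 4], [5, 6]])
        assert r.bms == pytest.approx(8.0)
        assert r.wms == pytest.approx(0.5)
        assert r.icc == pytest.approx(7.5 / 8.5, abs=1e-9)

    def test_pure_disagreement(self):
        r = icc_1_1([[1, 2], [2, 1]])
        assert r.bms == pytest.approx(0.0)
        assert r.icc == pytest.approx(-1.0, abs=1e-9)

    def test_all_identical_undefined(self):
        with pytest.raises(ValueError, match="identical"):
            icc_1_1([[2, 2], [2, 2]])

    def test_bounds_and_affine_invariance(self, rng):
        for _ in range(30):
            x = rng.normal(0, 1, size=(6, 2))
            r1 = icc_1_1(x)
            assert -1.0 <= r1.icc <= 1.0
            r2 = icc_1_1(-2.5 * x + 7.0)
            assert r2.icc == pytest.approx(r1.icc, abs=1e-10)

    def test_matches_reference_anova_routine(self, rng):
        """ICC(1,1) agrees with pingouin's one-way random-effects ICC1 to 1e-10."""
        pingouin = pytest.importorskip("pingouin")
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(10, 3, size=(n, 2))
            res = pingouin.intraclass_corr(
                data=pd.DataFrame(
                    {
                        "subject": np.repeat(np.arange(n), 2),
                        "rater": np.tile([0, 1], n),
                        "score": x.ravel(),
                    }
                ),
                targets="subject",
                raters="rater",
                ratings="score",
            )
            expected = float(res.loc[res["Type"] == "ICC(1,1)", "ICC"].iloc[0])
            assert icc_1_1(x).icc == pytest.approx(expected, abs=1e-10)


class TestCategorizeIcc:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.963, "high"),
            (0.9, "high"),
            (0.899, "intermediate"),
            (0.6, "intermediate"),
            (0.599, "poor"),
            (-1.0, "poor"),
        ],
    )
    def test_boundaries(self, icc, expected):
        assert categorize_icc(icc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_icc(1.5)


class TestGroupAverage:
    def test_single_member(self):
        results = [cov_percent([10, 12, 14])]  # ~16.5% -> intermediate
        out = group_average_cov(results)
        assert out["intermediate"] == pytest.approx(results[0].cov_percent)
        assert np.isnan(out["small"]) and np.isnan(out["large"])

    def test_hand_means(self):
        fake = [
            cov_percent([100, 105, 110]),  # ~4.8% small
            cov_percent([100, 107, 114]),  # ~6.5% small
            cov_percent([10, 14, 18]),  # ~28.6% intermediate
            cov_percent([10, 20, 30]),  # 50% large
        ]
        out = group_average_cov(fake)
        smalls = [f.cov_percent for f in fake if f.category == "small"]
        assert out["small"] == pytest.approx(np.mean(smalls))
        assert out["large"] == pytest.approx(50.0, abs=0.1)


class TestSuitability:
    def test_all_at_population_mean(self):
        table = pd.DataFrame({"condition": ["c1"] * 5, "f": [10.0] * 5})
        bounds = synth_population_bounds(["f"], means={"f": 10.0}, sds={"f": 1.0})
        detail, overall = suitability_percent(table, bounds, ["f"])
        assert overall == 100.0

    def test_closed_interval_membership(self):
        table = pd.DataFrame({"condition": ["c"] * 2, "f": [0.0, 5.0]})
        bounds = synth_population_bounds(["f"], means={"f": 2.0}, sds={"f": 1.0})
        detail, overall = suitability_percent(table, bounds, ["f"])  # bounds [0, 4]
        assert overall == 50.0

    def test_empty_table_rejected(self):
        bounds = synth_population_bounds(["f"], means={"f": 0.0}, sds={"f": 1.0})
        with pytest.raises(ValueError):
            suitability_percent(pd.DataFrame(), bounds, ["f"])

    def test_missing_bound_rejected(self):
        table = pd.DataFrame({"condition": ["c"], "g": [1.0]})
        bounds = synth_population_bounds(["f"], means={"f": 0.0}, sds={"f": 1.0})
        with pytest.raises(KeyError):
            suitability_percent(table, bounds, ["g"])


class TestHeatmap:
    def test_minmax_rescale_row(self):
        tab = pd.DataFrame({"a": [10.0, 5.0], "b": [20.0, 5.0], "c": [30.0, 5.0]},
                           index=["f1", "f2"])
        scaled, order = heatmap_matrix(tab)
        np.testing.assert_allclose(scaled.loc["f1"].to_numpy(), [0.0, 0.5, 1.0])

    def test_constant_row_all_zero(self):
        tab = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 6.0]}, index=["const", "x"])
        scaled, _ = heatmap_matrix(tab)
        np.testing.assert_array_equal(scaled.loc["const"].to_numpy(), [0.0, 0.0])

    def test_order_is_permutation(self, rng):
        tab = pd.DataFrame(
            rng.random((10, 4)), index=[f"f{i}" for i in range(10)]
        )
        scaled, order = heatmap_matrix(tab)
        assert sorted(order) == sorted(tab.index)
        assert list(scaled.index) == order

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            heatmap_matrix(pd.DataFrame({"a": [1.0]}, index=["f"]))
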