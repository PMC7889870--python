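"""Robustness statistics: COV variability, ICC(1,1) repeatability, suitability.

The three questions asked of every feature:

* **Variability** - how much does the feature move when one scan parameter
  (NEX, slice thickness, FOV) is swept over its settings?  Quantified by the
  coefficient of variation COV = (sigma / mu) * 100 across the settings, and
  bucketed as small (COV <= 10%), intermediate (10% < COV <= 30%) or large
  (COV > 30%).
* **Repeatability** - does a test-retest pair of scans under identical
  settings return the same value?  Quantified by the one-way random-effects
  intraclass correlation ICC(1,1) = (BMS - WMS) / (BMS + WMS), bucketed as
  high (ICC >= 0.9), intermediate (0.6 <= ICC < 0.9) or poor (ICC < 0.6).
* **Suitability** - does the phantom produce feature values inside the
  mean +/- 2 SD envelope of a reference patient population?

The module also builds the clustered COV heat map (per-feature 0-1 rescale,
Euclidean-distance hierarchical clustering of feature rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .phantom import PopulationBounds

__all__ = [
    "CovResult",
    "IccResult",
    "RobustnessReport",
    "cov_percent",
    "categorize_cov",
    "icc_1_1",
    "categorize_icc",
    "suitability_percent",
    "group_average_cov",
    "heatmap_matrix",
]

COV_CATEGORIES = ("small", "intermediate", "large")
ICC_CATEGORIES = ("high", "intermediate", "poor")


@dataclass(frozen=True)
class CovResult:
    feature: str
    family: str
    mu: float
    sigma: float
    cov_percent: float
    category: str


@dataclass(frozen=True)
class IccResult:
    feature: str
    bms: float
    wms: float
    icc: float
    category: str


def categorize_cov(cov: float) -> str:
    """small: COV <= 10%; intermediate: 10% < COV <= 30%; large: COV > 30%."""
    if not np.isfinite(cov) or cov < 0:
        raise ValueError(f"COV must be a finite non-negative percentage, got {cov}")
    if cov <= 10.0:
        return "small"
    if cov <= 30.0:
        return "intermediate"
    return "large"


def cov_percent(
    values, feature: str = "", family: str = ""
) -> CovResult:
    """Coefficient of variation (%) of one feature across a family's settings.

    sigma is the sample SD (n-1 denominator).  Features whose mean can be
    negative (e.g. ClusterShade) use |mu| in the denominator so the COV stays
    a non-negative percentage.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("COV needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("COV input contains non-finite values")
    mu = float(x.mean())
    if mu == 0:
        raise ValueError("COV undefined: mean is zero")
    sigma = float(x.std(ddof=1))
    cov = 100.0 * sigma / abs(mu)
    return CovResult(feature, family, mu, sigma, cov, categorize_cov(cov))


def categorize_icc(icc: float) -> str:
    """high: ICC >= 0.9; intermediate: 0.6 <= ICC < 0.9; poor: ICC < 0.6."""
    if not np.isfinite(icc) or not -1.0 - 1e-12 <= icc <= 1.0 + 1e-12:
        raise ValueError(f"ICC must lie in [-1, 1], got {icc}")
    if icc >= 0.9:
        return "high"
    if icc >= 0.6:
        return "intermediate"
    return "poor"


def icc_1_1(paired, feature: str = "") -> IccResult:
    """ICC(1,1) from a one-way random-effects ANOVA on an n x k table.

    Rows are subjects (here: ROI x protocol-condition pairs), columns are the
    k repeated scans (k = 2 for a test-retest pair).  BMS is the
    between-subjects mean square, WMS the within-subjects mean square;
    ICC = (BMS - WMS) / (BMS + (k - 1) WMS), which for k = 2 is the
    (BMS - WMS) / (BMS + WMS) form.
    """
    x = np.asarray(paired, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 subjects, k >= 2 replicates")
    if not np.isfinite(x).all():
        raise ValueError("ICC input contains non-finite values")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    bms = k * ((row_means - grand) ** 2).sum() / (n - 1)
    wms = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    if bms + wms == 0:
        raise ValueError("ICC undefined: all measurements identical")
    icc = (bms - wms) / (bms + (k - 1) * wms)
    return IccResult(feature, float(bms), float(wms), float(icc), categorize_icc(icc))


def group_average_cov(cov_results) -> dict[str, float]:
    """Arithmetic mean COV within each variation category; empty -> NaN."""
    out: dict[str, float] = {}
    for cat in COV_CATEGORIES:
        members = [r.cov_percent for r in cov_results if r.category == cat]
        out[cat] = float(np.mean(members)) if members else float("nan")
    return out


def suitability_percent(
    feature_table: pd.DataFrame,
    bounds: PopulationBounds,
    feature_columns: list[str] | None = None,
    condition_column: str = "condition",
) -> tuple[pd.DataFrame, float]:
    """Percentage of ROI feature values inside the population mean +/- 2 SD.

    For every (condition, feature) the fraction of ROI rows whose value lies
    in the closed interval is computed; fractions are averaged over features
    into one percentage per condition, and over conditions into the overall
    percentage.  Returns ``(per-condition/feature table, overall %)``.
    """
    if feature_table.empty:
        raise ValueError("feature table is empty")
    if feature_columns is None:
        feature_columns = [c for c in feature_table.columns if c in bounds.means]
        if not feature_columns:
            raise ValueError("no feature columns overlap the population bounds")
    missing = [f for f in feature_columns if f not in bounds]
    if missing:
        raise KeyError(f"no population bounds for features: {missing[:5]}")
    records = []
    group_cols = (
        [condition_column] if condition_column in feature_table.columns else []
    )
    grouped = feature_table.groupby(group_cols) if group_cols else [((), feature_table)]
    for cond, grp in grouped:
        cond_label = cond[0] if isinstance(cond, tuple) and cond else cond or "all"
        for f in feature_columns:
            lo, hi = bounds.lower(f), bounds.upper(f)
            vals = grp[f].to_numpy(dtype=float)
            inside = ((vals >= lo) & (vals <= hi)).mean()
            records.append(
                {"condition": cond_label, "feature": f, "percent_inside": 100.0 * inside}
            )
    detail = pd.DataFrame.from_records(records)
    overall = float(
        detail.groupby("condition")["percent_inside"].mean().mean()
    )
    return detail, overall


def heatmap_matrix(
    cov_table: pd.DataFrame, linkage_method: str = "average"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature 0-1 rescale of a features x conditions COV table, clustered.

    Each feature row is min-max rescaled to [0, 1] (constant rows map to all
    zeros); feature rows are ordered by agglomerative hierarchical clustering
    with Euclidean distance.  Returns the rescaled matrix in leaf order and
    the leaf-order feature names.
    """
    if cov_table.shape[0] < 2 or cov_table.shape[1] < 1:
        raise ValueError("need at least 2 features and 1 condition column")
    mat = cov_table.to_numpy(dtype=float)
    lo = mat.min(axis=1, keepdims=True)
    span = mat.max(axis=1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (mat - lo) / span, 0.0)
    scaled_df = pd.DataFrame(scaled, index=cov_table.index, columns=cov_table.columns)
    if cov_table.shape[1] == 1:
        order = list(cov_table.index)
    else:
        link = hierarchy.linkage(pdist(scaled, metric="euclidean"), method=linkage_method)
        order = [cov_table.index[i] for i in hierarchy.leaves_list(link)]
    return scaled_df.loc[order], list(order)


@dataclass
class RobustnessReport:
    """Everything the study computes, ready for writing/plotting."""

    cov_results: list[CovResult]
    icc_results: list[IccResult]
    group_averages: dict[str, float]
    suitability_detail: pd.DataFrame | None
    suitability_overall: float | None
    heatmap: pd.DataFrame | None
    heatmap_order: list[str] | None

    def cov_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.cov_results])

    def icc_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.icc_results])

    def average_icc(self) -> float:
        return float(np.mean([r.icc for r in self.icc_results]))
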