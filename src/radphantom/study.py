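"""Study orchestration: simulate the protocol grid, extract features, report.

The default experiment mirrors a one-factor-at-a-time protocol sweep: each
scan parameter family (NEX, slice thickness, FOV) is varied over its three
settings while the others stay at their defaults, every condition is
acquired twice (test-retest, with the phantom repositioned between scans),
and all 20 insert ROIs are measured in every scan.

Analyses:

* variability - per (feature, family): the COV across the family's settings
  is computed per ROI on the first scan and averaged over ROIs;
* repeatability - per feature: ICC(1,1) with rows = (ROI x condition) and
  columns = the two repeated scans, pooled over the whole grid;
* suitability - fraction of ROI values inside synthetic patient-population
  mean +/- 2 SD bounds, per condition and overall;
* the clustered COV heat map across families.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ALL_FEATURES, FeatureConfig, extract_all_features
from .image import ImageVolume
from .phantom import (
    PhantomSpec,
    PopulationBounds,
    build_phantom,
    make_cylindrical_roi,
    synth_population_bounds,
)
from .robustness import (
    CovResult,
    IccResult,
    RobustnessReport,
    categorize_cov,
    cov_percent,
    group_average_cov,
    heatmap_matrix,
    icc_1_1,
    suitability_percent,
)
from .scan import DEFAULT_FAMILIES, ScanProtocol, one_factor_grid, simulate_scan

__all__ = [
    "StudyConfig",
    "run_full_study",
    "simulate_feature_table",
    "analyze_feature_table",
    "write_feature_table",
    "read_feature_table",
    "META_COLUMNS",
]

log = logging.getLogger("radphantom")

META_COLUMNS = [
    "roi_id",
    "material_id",
    "sequence",
    "scanner_tag",
    "condition",
    "family",
    "replicate",
    "preprocess_arm",
]


@dataclass
class StudyConfig:
    """Everything needed to reproduce a run: grid, arms, seeds.

    ``reposition_amplitude`` is the test-retest jitter: the second scan sees
    the phantom translated by a uniform sub-voxel shift in
    [-amplitude, amplitude] mm per axis.
    """

    sequences: tuple[str, ...] = ("T1like",)
    scanners: tuple[str, ...] = ("siemens",)
    families: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    matrix: int = 192
    noise_sigma: float | None = None  # None -> scanner preset
    roi_diameter: float = 18.0
    roi_height: float = 100.0
    reposition_amplitude: float = 1.0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    population_sd_inflation: float = 2.0
    output_dir: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["feature_config"] = asdict(self.feature_config)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        fc = doc.pop("feature_config", {})
        for key in ("glcm_offsets", "glrl_directions"):
            if key in fc:
                fc[key] = tuple(tuple(v) for v in fc[key])
        cfg = cls(**{**doc, "feature_config": FeatureConfig(**fc)})
        cfg.sequences = tuple(cfg.sequences)
        cfg.scanners = tuple(cfg.scanners)
        cfg.families = {
            k: (tuple(v[0]), v[1]) for k, v in cfg.families.items()
        }
        return cfg


def _jitter(rng: np.random.Generator, amplitude: float) -> tuple[float, float, float]:
    if amplitude == 0:
        return (0.0, 0.0, 0.0)
    return tuple(rng.uniform(-amplitude, amplitude, 3))


def simulate_feature_table(
    config: StudyConfig, phantom_spec: PhantomSpec | None = None
) -> pd.DataFrame:
    """Simulate the full grid and extract features from every scan's ROIs.

    Returns a long-format table: one row per (ROI, condition, replicate)
    with the metadata columns followed by the 76 feature columns.
    """
    spec = phantom_spec or PhantomSpec()
    master = np.random.SeedSequence(config.seed)
    seq_seeds = master.spawn(len(config.sequences) * len(config.scanners) + 1)
    rows: list[dict] = []
    idx = 0
    for sequence in config.sequences:
        for scanner in config.scanners:
            ss = seq_seeds[idx]
            idx += 1
            phantom_seed, scan_entropy = ss.spawn(2)
            truth, insert_masks = build_phantom(
                spec, seed=int(phantom_seed.generate_state(1)[0] % 2**31), sequence=sequence
            )
            base = ScanProtocol.for_scanner(
                scanner, sequence=sequence, matrix=config.matrix
            )
            if config.noise_sigma is not None:
                base = replace(base, noise_sigma=config.noise_sigma)
            conditions, members = one_factor_grid(base, config.families)
            cond_families = {
                key: sorted(f for f, keys in members.items() if key in keys)
                for key in conditions
            }
            cond_seeds = scan_entropy.spawn(len(conditions))
            for (key, proto), cseed in zip(conditions.items(), cond_seeds):
                rep_seeds = cseed.spawn(3)
                jitter_rng = np.random.default_rng(rep_seeds[2])
                for replicate in (1, 2):
                    shift = (
                        (0.0, 0.0, 0.0)
                        if replicate == 1
                        else _jitter(jitter_rng, config.reposition_amplitude)
                    )
                    noise_seed = int(
                        rep_seeds[replicate - 1].generate_state(1)[0] % 2**31
                    )
                    scan = simulate_scan(truth, proto, reposition=shift, seed=noise_seed)
                    log.info(
                        "scan %s replicate %d shift=%s seed=%d", key, replicate, shift,
                        noise_seed,
                    )
                    for center, imask in zip(spec.insert_centers, insert_masks):
                        roi_center = tuple(c + s for c, s in zip(center, shift))
                        roi = make_cylindrical_roi(
                            roi_center,
                            config.roi_diameter,
                            config.roi_height,
                            scan,
                            label=imask.label,
                        )
                        fv = extract_all_features(scan, roi, config.feature_config)
                        row = {
                            "roi_id": imask.label,
                            "material_id": imask.label,
                            "sequence": sequence,
                            "scanner_tag": scanner,
                            "condition": key,
                            "family": "+".join(cond_families[key]),
                            "replicate": replicate,
                            "preprocess_arm": config.feature_config.arm,
                        }
                        row.update(fv.values)
                        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + ALL_FEATURES)


def _family_members(config: StudyConfig, scanner: str, sequence: str) -> dict[str, list[str]]:
    base = ScanProtocol.for_scanner(scanner, sequence=sequence, matrix=config.matrix)
    if config.noise_sigma is not None:
        base = replace(base, noise_sigma=config.noise_sigma)
    _, members = one_factor_grid(base, config.families)
    return members


def analyze_feature_table(
    table: pd.DataFrame,
    config: StudyConfig,
    bounds: PopulationBounds | None = None,
) -> RobustnessReport:
    """COV, ICC, suitability and heat map from a simulated feature table."""
    if table.empty:
        raise ValueError("feature table is empty")
    cov_results: list[CovResult] = []
    heat_cols: dict[str, pd.Series] = {}
    for (sequence, scanner), grp in table.groupby(["sequence", "scanner_tag"]):
        members = _family_members(config, scanner, sequence)
        first = grp[grp["replicate"] == 1]
        for family, keys in members.items():
            sweep = first[first["condition"].isin(keys)]
            col = {}
            for feat in ALL_FEATURES:
                per_roi = []
                for _, roi_grp in sweep.groupby("roi_id"):
                    vals = roi_grp.set_index("condition").loc[keys, feat].to_numpy()
                    try:
                        per_roi.append(cov_percent(vals, feat, family).cov_percent)
                    except ValueError:
                        continue
                if not per_roi:
                    continue
                avg = float(np.mean(per_roi))
                col[feat] = avg
                cov_results.append(
                    CovResult(
                        feature=feat,
                        family=f"{scanner}|{sequence}|{family}",
                        mu=float("nan"),
                        sigma=float("nan"),
                        cov_percent=avg,
                        category=categorize_cov(avg),
                    )
                )
            heat_cols[f"{scanner}|{sequence}|{family}"] = pd.Series(col)

    icc_results: list[IccResult] = []
    icc_undefined: list[str] = []
    wide = table.pivot_table(
        index=["sequence", "scanner_tag", "roi_id", "condition"],
        columns="replicate",
        values=ALL_FEATURES,
    )
    for feat in ALL_FEATURES:
        pairs = wide[feat].to_numpy(dtype=float)
        try:
            icc_results.append(icc_1_1(pairs, feature=feat))
        except ValueError:
            icc_undefined.append(feat)

    group_avg = group_average_cov(cov_results)

    suit_detail = None
    suit_overall = None
    if bounds is None:
        ref = table[table["replicate"] == 1]
        bounds = synth_population_bounds(
            ALL_FEATURES,
            reference_values=ref[ALL_FEATURES],
            sd_inflation=config.population_sd_inflation,
        )
    suit_detail, suit_overall = suitability_percent(
        table[table["replicate"] == 1], bounds, feature_columns=ALL_FEATURES
    )

    heat_df = pd.DataFrame(heat_cols).dropna()
    heat = order = None
    if heat_df.shape[0] >= 2 and heat_df.shape[1] >= 1:
        heat, order = heatmap_matrix(heat_df)

    report = RobustnessReport(
        cov_results=cov_results,
        icc_results=icc_results,
        group_averages=group_avg,
        suitability_detail=suit_detail,
        suitability_overall=suit_overall,
        heatmap=heat,
        heatmap_order=order,
    )
    report.icc_undefined = icc_undefined  # type: ignore[attr-defined]
    return report


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format feature table as CSV with a stable column order."""
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    cols = [c for c in META_COLUMNS if c in table.columns] + ALL_FEATURES
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ALL_FEATURES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing[:5]}")
    return table


def _write_markdown_categories(report: RobustnessReport, path: Path) -> None:
    lines = ["# Feature variation and repeatability categories", ""]
    lines += ["## Variability (COV)", "", "| category | features |", "|---|---|"]
    cov = report.cov_frame()
    if not cov.empty:
        best = cov.groupby("feature")["cov_percent"].mean()
        for cat, (lo, hi) in (
            ("small", (-1, 10)),
            ("intermediate", (10, 30)),
            ("large", (30, np.inf)),
        ):
            feats = sorted(best[(best > lo) & (best <= hi)].index)
            lines.append(f"| {cat} | {', '.join(feats) if feats else '-'} |")
    lines += ["", "## Repeatability (ICC)", "", "| category | features |", "|---|---|"]
    icc = report.icc_frame()
    if not icc.empty:
        for cat in ("high", "intermediate", "poor"):
            feats = sorted(icc[icc["category"] == cat]["feature"])
            lines.append(f"| {cat} | {', '.join(feats) if feats else '-'} |")
    path.write_text("\n".join(lines) + "\n")


def _render_heatmap(report: RobustnessReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(
        figsize=(4 + 0.5 * report.heatmap.shape[1], 0.18 * report.heatmap.shape[0] + 2)
    )
    sns.heatmap(report.heatmap, cmap="Blues", vmin=0, vmax=1, ax=ax,
                cbar_kws={"label": "rescaled COV"})
    ax.set_xlabel("scan-parameter family")
    ax.set_ylabel("feature (clustered)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_full_study(
    config: StudyConfig, phantom_spec: PhantomSpec | None = None
) -> RobustnessReport:
    """Simulate, extract, analyze and (optionally) persist the whole study.

    With ``config.output_dir`` set, writes ``feature_table.csv``,
    ``cov_results.csv``, ``icc_results.csv``, ``suitability.csv``,
    ``group_averages.csv``, ``categories.md``, ``heatmap.png`` and the
    resolved ``config.yaml``.
    """
    table = simulate_feature_table(config, phantom_spec)
    report = analyze_feature_table(table, config)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_feature_table(table, out / "feature_table.csv")
        report.cov_frame().to_csv(out / "cov_results.csv", index=False)
        report.icc_frame().to_csv(out / "icc_results.csv", index=False)
        if report.suitability_detail is not None:
            report.suitability_detail.to_csv(out / "suitability.csv", index=False)
        pd.Series(report.group_averages).rename("average_cov_percent").to_csv(
            out / "group_averages.csv"
        )
        _write_markdown_categories(report, out / "categories.md")
        if report.heatmap is not None:
            _render_heatmap(report, out / "heatmap.png")
        summary = {
            "average_icc": report.average_icc() if report.icc_results else None,
            "suitability_overall_percent": report.suitability_overall,
            "group_average_cov_percent": {
                k: (None if np.isnan(v) else v) for k, v in report.group_averages.items()
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    report.feature_table = table  # type: ignore[attr-defined]
    return report
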