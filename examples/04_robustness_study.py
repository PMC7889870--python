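"""Run a reduced robustness study and summarize COV, ICC and suitability.

For speed this example sweeps only the NEX family (two settings); the full
default study (`StudyConfig()` / `radphantom run-all`) sweeps NEX, slice
thickness and FOV over 7 distinct conditions with test-retest duplicates.
"""

from radphantom import StudyConfig, analyze_feature_table, simulate_feature_table

cfg = StudyConfig(families={"nex": ((1, 3), 1)}, seed=11)
table = simulate_feature_table(cfg)
report = analyze_feature_table(table, cfg)

print(f"feature table: {len(table)} rows "
      f"({table.condition.nunique()} conditions x 2 replicates x 20 ROIs)")
print(f"average ICC(1,1): {report.average_icc():.3f}")
icc = report.icc_frame()
print("repeatability categories:", icc.category.value_counts().to_dict())
cov = report.cov_frame()
print("variation categories:", cov.category.value_counts().to_dict())
for cat, val in report.group_averages.items():
    print(f"group-average COV [{cat}]: {val:.2f}%")
print(f"suitability (inside population mean +/- 2 SD): "
      f"{report.suitability_overall:.1f}%")
# A high average ICC means a repeated scan under identical settings returns
# nearly the same feature values; the COV categories tell you which features
# drift when the protocol changes and should be used with caution.
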