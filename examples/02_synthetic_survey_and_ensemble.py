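"""Simulate a survey, train the bootstrap forest ensemble, evaluate it.

Generates a small LUCAS-like synthetic survey with a known covariate →
degradation link, computes the SDP, trains a 10-member bootstrap
random-forest ensemble on a 70/30 split and prints train/validation
accuracy plus the most important predictors.
"""

from sdproxy import (
    EnsembleConfig,
    SyntheticConfig,
    build_sdp_table,
    ensemble_metrics,
    generate_covariate_grids,
    generate_survey,
    train_ensemble,
    variable_importance,
)

cfg = SyntheticConfig(grid_rows=32, grid_cols=32, n_points_per_year=400, seed=42)
stack = generate_covariate_grids(cfg)
table = build_sdp_table(generate_survey(stack, cfg))
print(f"survey: {len(table)} rows over years {sorted(table['year'].unique())}")

ens = train_ensemble(table, EnsembleConfig(n_models=10, n_trees=100, seed=42))
report = ensemble_metrics(ens, table)
print("\nmean metrics over the 10 members:")
print(report.ensemble_means.to_string(index=False))

print("\ntop predictors (normalized Gini importance):")
print(variable_importance(ens).head(5).round(3).to_string())
print(
    "\nValidation R^2 close to 1 means the ensemble recovered the planted\n"
    "covariate–degradation link; importance shares sum to 1."
)
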