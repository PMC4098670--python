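"""Summarize a trained map: persistence, seasonality, reliability, layout.

Per-class summaries are keyed by map node so they can be read off the grid:
run durations show how long day types persist, seasonal tables show when
they occur, the within-class CV flags high-dispersion classes, and the
codebook dendrogram confirms that similar day types are map neighbors.
"""

import numpy as np
from scipy.spatial.distance import cdist

from airsom import (
    SOMGrid,
    TrainingSchedule,
    class_reliability,
    codebook_dendrogram,
    complete_case_filter,
    generate,
    generate_covariates,
    covariate_summary,
    grid_summary_export,
    persistence,
    seasonal_frequencies,
    standardize,
    table1_profile,
    train_with_restarts,
)

Z, truth = generate(table1_profile(seed=3))
Zc = complete_case_filter(Z)
Zs, params = standardize(Zc)
model = train_with_restarts(
    Zs.values, SOMGrid(4, 4), TrainingSchedule(seed=3),
    n_restarts=10, standardization=params, columns=Zc.columns,
)

runs = persistence(model.assignments, Zc.dates)
overall = runs["total_days"].sum() / runs["n_runs"].sum()
print(f"mean day-type duration: {overall:.2f} days "
      f"(per-class means {runs['mean_length'].min():.2f}"
      f"..{runs['mean_length'].max():.2f})")

seasonal = seasonal_frequencies(model.assignments, Zc.dates,
                                classes=range(model.k))
winter_heavy = seasonal["DJF"].idxmax()
summer_heavy = seasonal["JJA"].idxmax()
print(f"most wintry day type: node {model.grid.labels[winter_heavy]}, "
      f"most summery: node {model.grid.labels[summer_heavy]}")

cv = class_reliability(Zs.values, model, se_convention="as_printed")
print(f"within-class CV range: {cv['cv_percent'].min():.2f}%"
      f"..{cv['cv_percent'].max():.2f}% (lower = tighter class)")

tree = codebook_dendrogram(model)
a, b = int(tree.linkage[0, 0]), int(tree.linkage[0, 1])
grid_dist = np.linalg.norm(model.grid.coords[a] - model.grid.coords[b])
print(f"first dendrogram merge joins nodes {tree.leaf_labels[a]} and "
      f"{tree.leaf_labels[b]} (grid distance {grid_dist:.2f}) — "
      "similar day types sit together on the map")

cov = generate_covariates(truth[Z.row_mask_complete()], Zc.dates, seed=3)
summary = covariate_summary(model.assignments, Zc.dates, cov)
print("\nper-class weather means (first 4 classes):")
print(summary.xs("mean", axis=1, level="stat").head(4).round(1).to_string())

table = grid_summary_export(
    model, {"persistence": runs.reindex(range(model.k))}
)
print(f"\ngrid-keyed export has {len(table)} rows (one per node)")
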