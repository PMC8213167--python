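"""Run the feature-selection cascade on a case/control cohort.

The cohort elevates one population (neutrophil-like) in case samples. The
cascade — collinearity and variance filters, PCA, L1 coefficient path,
depth-1 gini tree, Mann-Whitney with Holm correction — should converge on
that population from three independent directions.
"""
import numpy as np

import autocyto as ac
from autocyto.features import (
    collinearity_filter,
    group_compare,
    l1_path,
    pca_report,
    tree_report,
    variance_filter,
)

spec = ac.flagship_cohort(seed=9)
samples = ac.generate_cohort(spec)
project = ac.cohort_to_project(samples, spec)
exp = next(iter(project.experiments.values()))
for s in samples:  # oracle populations from the generator's truth labels
    fg = exp.filegroups[s.sample_id]
    for p in spec.populations:
        idx = np.flatnonzero(s.true_labels == p.name)
        fg.add_population(ac.Population(p.name, "root", idx,
                                        source="cluster"))

ft = ac.extract_features(project, "panel_a",
                         [p.name for p in spec.populations],
                         statistics=("fraction_of_root",),
                         metadata_covariates=("age",))
ft, dropped = collinearity_filter(ft, 0.9)
ft, _ = variance_filter(ft, 0.02)
pca = pca_report(ft, n_components=2)
path = l1_path(ft, seed=9)
tree = tree_report(ft, max_depth=1, seed=9)
stats = group_compare(ft)

print(f"features after filters: {ft.feature_names}")
print(f"PC1 explains {pca.explained_variance_ratio[0] * 100:.1f}% of "
      f"variance; top |PC1| loading: {pca.loadings.loc['PC1'].abs().idxmax()}")
print(f"most persistent L1 feature: {path.ranking[0]}")
print(f"tree root split: {tree.root_feature} <= {tree.root_threshold:.4f} "
      f"(training accuracy {tree.training_accuracy:.2f})")
print(stats.round(4).to_string(index=False))
print("All three selectors and the Holm-corrected rank test point at the "
      "case-elevated population.")
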