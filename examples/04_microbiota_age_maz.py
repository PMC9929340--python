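"""Fit the microbiota-age model and compute MAZ scores.

The cohort is partitioned into healthy-reference children (HIV-unexposed,
not stunted at 18 months) and everyone else; a gradient-boosted model is
trained on log age of the reference children, and each child's predicted
("microbiota") age is standardized against the per-visit reference
distribution to give the microbiota-for-age Z-score (MAZ).
"""

from micromature.feature_table import SPECIES_FILTER, filter_features
from micromature.maturity import (
    SearchConfig,
    build_reference,
    compare_maturity,
    compute_maz_scores,
    fit_age_model,
    partition_cohort,
)
from micromature.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_children=100, seed=7))
species = filter_features(cohort.species, SPECIES_FILTER)

part = partition_cohort(cohort.metadata)
print(f"healthy train: {len(part.healthy_train)} samples, "
      f"healthy test: {len(part.healthy_test)}, unhealthy: {len(part.unhealthy)}")

res = fit_age_model(species, cohort.metadata, part, SearchConfig.desk_scale(seed=7))
for subset, metrics in sorted(res.metrics.items()):
    print(f"{subset:>13}: pseudo-R2 = {metrics['pseudo_r2']:.2f}, "
          f"MAE = {metrics['mae']:.2f} months")
# Training metrics come from out-of-fold predictions, so they are honest;
# MAE is the typical error of the predicted age in months.

train_pred = res.predictions.loc[
    res.predictions["set"] == "healthy_train", "predicted_age_months"
]
reference = build_reference(train_pred, cohort.metadata)
scores = compute_maz_scores(res.predictions["predicted_age_months"],
                            cohort.metadata, reference)
print(f"\nMAZ computed for {scores['maz'].notna().sum()} samples; "
      f"reference-set median MAZ = {scores.loc[train_pred.index, 'maz'].median():+.2e}")

contrast = compare_maturity(scores, cohort.metadata)
print("\nCHEU vs CHU maturity contrast (covariate-adjusted):")
print(contrast.to_string(index=False))
# beta > 0 would mean CHEU children look microbially older than CHU
# children of the same visit.
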