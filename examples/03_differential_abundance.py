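"""Covariate-adjusted differential abundance of species between CHEU and CHU
children at one age category, with Benjamini-Hochberg FDR control."""

from micromature.differential_abundance import results_to_frame, run_differential_abundance
from micromature.feature_table import SPECIES_FILTER, filter_features
from micromature.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_children=150, seed=3))
species = filter_features(cohort.species, SPECIES_FILTER)

meta = cohort.metadata[cohort.metadata["hiv_exposure"].isin(["CHEU", "CHU"])].copy()
meta["cheu"] = (meta["hiv_exposure"] == "CHEU").astype(float)
at6 = meta[meta["age_category"] == 6]

results = run_differential_abundance(
    species.subset_samples([s for s in at6["sample_id"] if s in species.data.index]),
    at6,
    phenotype="cheu",
)
frame = results_to_frame(results)
print(frame.head(8).to_string(index=False))
# beta < 0 means lower abundance in CHEU after adjusting for age, feeding,
# delivery mode and trial arm; q is the BH-adjusted p-value.
planted = frame[frame["feature"].str.startswith("Bifidobacterium_b")]
print("\nplanted CHEU-depleted species:")
print(planted.to_string(index=False))
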