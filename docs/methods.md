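# Methods

This note documents the models and procedures implemented in `micromature`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A **feature table** is a samples × features matrix of relative abundances
(fractions in [0, 1]); rows may sum to less than one because the
unannotated fraction of a metagenome is real and is not stored as a
feature. Tables are read/written in the merged-profiler dialect (feature
IDs in column 1, one column per sample), with an explicit unit flag —
percent inputs are converted to fractions on load, so every threshold in
the package is expressed as a fraction. **Metadata** is a validated pandas
DataFrame (one row per stool sample) with a documented column dictionary;
validation derives the combined trial-arm indicators (WASH vs non-WASH,
IYCF vs non-IYCF), age in months, and the age category of each sample.

### Feature filtering

A feature is retained when its maximum relative abundance across samples
exceeds `min_rel_abund` **and** it is detected in at least `min_prevalence`
of samples. Defaults: species 1e-3 (0.1 %) and 0.05; pathways 3e-9 and
0.05. The pathway abundance threshold is the literal fractional reading of
a "3 × 10⁻⁷ %" convention; it is so permissive that prevalence does the
work, and it is configurable because reasonable readings differ by two
orders of magnitude. Two deliberate choices:

* **No renormalization after filtering.** Retained abundances keep their
  profiled values, preserving cross-sample comparability; re-closing the
  composition after dropping features would silently change every value.
* **Detection threshold 0** for prevalence: any nonzero abundance counts
  as "detected", since profilers already apply their own detection floor.

### Age categories

Samples are re-binned into six categories reflecting developmental stages,
with month = 30.4375 days: 1 month (0–6 weeks), 2 months (7 weeks to <3
months), 3 months (3–6 months), 6 months (6–9 months), 12 months (9–15
months), 18 months (15–20 months). Lower bounds are inclusive, upper bounds
exclusive, except day 42 (belongs to "1 month") and the 20-month cap
(inclusive); older samples are flagged out-of-range and excluded
downstream. The binning is total and monotone over the valid range.

## Diversity

Shannon diversity is −Σ pᵢ ln pᵢ over the renormalized composition (nats;
the log base is configurable since conventions differ), Pielou evenness
H/ln(richness) (undefined below two detected taxa), and richness a simple
detection count at a configurable threshold — applied to species tables for
species richness and pathway tables for gene richness. Bray-Curtis
distances and PCoA use scipy/scikit-bio; negative eigenvalues of the
double-centered Gram matrix are reported, never silently dropped.

PERMANOVA is implemented in-package so the permutation scheme is explicit:
pseudo-F = (SSA/(a−1))/(SSW/(N−a)) from among/within sums of squared
distances, R² = SSA/SST, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) with
seeded label permutations. The add-one correction means p can never be 0;
ties count toward the null (conservative). Only a single grouping factor is
supported — the intended use is one test per age category. The two-group
location permutation test (for unbalanced alpha-diversity comparisons) uses
the absolute difference in means with the same add-one convention. Tests
cross-check the pseudo-F against scikit-bio's PERMANOVA and the p-values
against exhaustive enumeration at small n.

## Differential abundance

A generic covariate-adjusted stage, not a clone of any specific package:
per feature, abundances are log-transformed after replacing zeros with half
the feature's minimum nonzero value (all-zero features are skipped and
logged); an OLS regression of the transformed abundance on the phenotype
plus adjustment covariates gives the phenotype β and two-sided p; BH
step-up q-values control FDR across features, with the conventional
significance flag p < 0.05 and q < 0.25 (both configurable). The default
covariate set is age in days, exclusive breastfeeding at 3 months,
caesarean delivery, and randomized trial arm (four-level factor, SOC
reference). Within an age category one sample per child (the earliest) is
used to avoid pseudo-replication; samples with missing covariates are
dropped listwise with logged counts. Limitations by design: no
zero-inflated or log-ratio models, no random effects — repeated measures
are handled by analyzing age categories separately.

## Staged gradient-boosting selection

The selection protocol around the XGBoost regressor:

1. **Stage 1** — `n_iterations` hyperparameter configurations are evaluated
   by k-fold (default 10) cross-validated MSE. The search backend is
   either expected-improvement Bayesian optimization over a
   Gaussian-process surrogate (Matérn 5/2 on the unit-cube-encoded
   parameters, 256 random candidates per proposal) or plain random search;
   only the selection rules downstream depend on which. Configurations
   with MSE at or below the 5th percentile of the evaluated set are
   retained (`model_retention_quantile = 0.05`, interpreted within one
   seeded search); their gain importances, summed over retained models, are
   ranked and the features covering the top 95 % of cumulative importance
   are kept (`importance_retention_fraction = 0.95`), applied separately to
   the microbiome and epidemiological feature groups so that one group
   cannot crowd out the other. A retention fraction of 1 keeps every
   feature, including zero-importance ones (identity filter); a group whose
   total importance is zero is kept intact, since there is no information
   to filter on.
2. **Stage 2** — the search is repeated on the retained features with
   leave-one-out CV, and the importance filter is applied again (stage-2
   features are therefore a subset of stage-1 features). Above
   `max_loocv_n` (default 60) samples, LOOCV falls back to k-fold with a
   warning; this keeps the scheme exact at reference scale while making
   desk-scale runs feasible.
3. **Stage 3** — the stage-2 winning configuration is refitted; out-of-fold
   predictions over the training set give the reported pseudo-R², MAE and
   MSE (every training sample is predicted by a model that never saw it,
   and the fold bookkeeping is recorded so tests can verify this), and a
   final model refitted on all training data scores any held-out set.

Hyperparameter ranges (depth 2–8, learning rate 0.01–0.3 log-scaled,
50–500 rounds, subsample 0.5–1, column subsample 0.3–1, L1/L2 0–5) are
conventional for sparse omics tables and fully configurable.
`SearchConfig.desk_scale()` (8 iterations, 50–200 rounds) is the
configuration used for the bundled synthetic cohorts and the test suite.
With `tree_method="hist"`, one thread and fixed seeds, the whole procedure
is deterministic.

A constant response is handled without crashing: with zero outcome
variance the reported pseudo-R² is 0 for perfect prediction and −∞
otherwise (both ≤ 0), and empty importance keeps the feature set intact.

## Microbiota age and MAZ

Children are partitioned by three rules: unexposed (CHU) children with
18-month LAZ > −2 contributing more than one sample form the **healthy
training set**; such children with a single sample the **healthy test
set**; everyone else (HIV-exposed, stunted at 18 months, HIV-positive or
unknown status) the **unhealthy test set**. Children with missing 18-month
LAZ are assigned unhealthy — conservative, since the reference must never
be contaminated — and samples with missing age are excluded. All samples of
a child fall on one side of the partition.

The age model regresses log(age in months) on the (filtered) feature table
over the healthy training set via the staged selection; predictions are
exponentiated to months, so they are strictly positive. Metrics are
reported per set on the months scale: training metrics from out-of-fold
predictions, test-set metrics from the final refitted model.

The **maturity reference** is the per-scheduled-visit median and SD of the
healthy-reference predicted ages — the visit label, not the derived age
category, indexes the reference, because the reference is meant to absorb
the within-visit age spread. Visits with fewer than two reference children
or zero SD are flagged unusable and produce missing scores. MAZ (or MetAZ
for pathway models) is (predicted age − visit median)/visit SD; by
construction the reference set's per-visit median MAZ is exactly 0.
Exposure contrasts regress MAZ (or predicted age) on a CHEU indicator with
the standard covariate set, per age category, excluding HIV-positive/
unknown children.

## Growth models

Growth velocity is (Z_next − Z_current)/(age_next − age_current) in
Z-score units per day, assigned to the *earlier* visit of each pair — the
model predicts future growth from the current microbiome — and missing at
each child's final visit; non-increasing ages or duplicate visits within a
child are errors, not silent repairs. The task grid crosses outcome
(LAZ, WHZ, LAZ velocity, WHZ velocity) × age category × maternal-HIV
stratum × feature set (microbiome only / plus epidemiology) × feature kind
(species / pathways). Within a cell, one sample per child (earliest) is
used; cells below `min_n = 15` usable samples are skipped with an explicit
"unstable stratum" status rather than fitted. Epidemiological categoricals
are one-hot encoded (trial arm with SOC reference). Each fitted cell
reports out-of-fold pseudo-R², MAE, and the top-20 scaled importances.

## Interpretation

Scaled importance divides gain importances by the maximum, so the most
informative feature is 1 and the rest are relative to it (top 20 by
default). ALE uses quantile (equal-count) intervals, matching the
"percentile of the abundance distribution" axis of the plots it supports;
tied breakpoints — ubiquitous at zero abundance — are merged. The effect is
attached to interval right edges and centered by the sample-weighted mean
of the accumulated curve interpolated at interval midpoints, which makes
the weighted mean of the centered curve zero to machine precision. The
per-increment CI is mean ± 1.96·sd/√n where sd is the SD of the
*per-sample* prediction changes within the interval — a design choice; a
bootstrap over refits would capture model variance too, at many times the
cost. A constant feature returns a zero curve with a warning.

## Synthetic cohort generator

The generator produces what the analysis assumes, with a seeded generator
and per-child sub-streams (independent streams per purpose, so exposure
assignment can never share random bits with growth noise):

* **Composition**: log-normal latent abundances, uniform Bernoulli zero
  inflation (default 30 % zeros), and closure of each row to 1 minus a
  drawn unannotated remainder (2–15 %). A fifth of the filler features
  forms a rare tail far below the community, so the species filter has
  real work to do.
* **Succession**: three Bifidobacterium-like dominant early taxa decline
  with age while late fermenters and a broad set of colonizers rise; age
  trends act on a saturating scale, 5·ln(1 + months), because assembly is
  rapid in the first months and slows toward 18 months — a linear scale
  concentrates the late community onto the fastest growers and makes
  diversity fall with age, the opposite of the structure being emulated.
  Succession is mostly colonization (40 rising vs 20 declining filler
  species), so Shannon diversity rises from the Bifidobacterium-dominated
  start and then plateaus.
* **Exposure**: ~30 % of children are CHEU (Bernoulli per child), with
  planted depletion of two Bifidobacterium species and a compositional
  flattening that raises CHEU diversity; ~1 % HIV-positive and ~2 %
  HIV-unknown children exercise the exclusion bookkeeping.
* **Sampling**: five scheduled visits (1, 3, 6, 12, 18 months) with 15-day
  age jitter — so re-binning into the six age categories is exercised
  nontrivially — ~10 % missed visits, and ~20 % of children contributing a
  single sample (as happens when part of a cohort enters through an
  ancillary study); single-sample healthy children are what populates the
  healthy test set.
* **Growth**: per-child LAZ trajectories (random intercept and negative
  age slope — growth faltering) plus planted pathway effects (three
  B-vitamin/nucleotide-synthesis-like pathways, coefficients per SD of log
  abundance), birthweight and maternal height effects, and sample-level
  noise; the whole LAZ scale is shifted by an empirical quantile so that
  the 18-month stunting fraction matches the configured target (default
  30 %) without breaking the causal pathway→LAZ links. WHZ is generated
  analogously with its own planted pathways.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: phylogenetic or strain structure, taxon
covariance beyond the planted effects (features are conditionally
independent given age/exposure/child), sequencing-depth artifacts,
batch effects, informative missingness, and any nonlinearity in the
pathway→growth links. Recovery results on synthetic cohorts demonstrate
that the machinery finds structure that is present at realistic noise
levels; they say nothing about whether real cohorts contain such structure.

## Problem sizes and reproducibility

The bundled analyses run on cohorts of 30–100 children (150–450 samples,
80–100 species, 60–80 pathways) with the desk-scale search configuration;
at these sizes the full test suite takes ~10 minutes and the acceptance
script ~1 minute on one CPU. One integer seed drives everything: cohort
generation, CV folds, the hyperparameter search, and every permutation
test. Identical seeds give byte-identical tables and identical metrics.

## Known limitations

* The differential-abundance stage is a linear model on log abundances; it
  ignores compositionality (no log-ratio transform) and repeated measures.
* PERMANOVA is univariate (one factor, no covariate adjustment or
  sequential decomposition) and reports no dispersion diagnostic.
* The 5th-percentile model-retention rule is interpreted within a single
  seeded search trajectory; with few iterations it often retains exactly
  the best configuration.
* MAZ requires a usable reference at each visit; small reference groups
  make the score noisy, and the package flags rather than fixes this.
* ALE for categorical features orders levels by outcome mean, a
  documented convention rather than a canonical definition.
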