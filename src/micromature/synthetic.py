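"""Synthetic longitudinal infant-cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any sequencing data:

* compositional species/pathway tables (rows sum to <= 1, the remainder is
  the unannotated fraction), log-normal abundances with zero inflation;
* age-structured succession — early *Bifidobacterium* dominance giving way
  to late-colonizing fermenters;
* longitudinal sampling of children over scheduled visit windows with
  age jitter and missed visits;
* maternal-HIV exposure effects on specific taxa and on overall diversity
  (CHEU = HIV-exposed uninfected children);
* growth outcomes (LAZ/WHZ) causally linked to a planted subset of pathway
  features plus epidemiological covariates, with a population-level LAZ
  decline over age (faltering trajectory) calibrated to a target stunting
  fraction at 18 months.

The ground truth (planted coefficients, latent trajectories) is returned as
:class:`SyntheticTruth` so that tests can score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_table import DAYS_PER_MONTH, FeatureTable, validate_metadata

__all__ = [
    "VisitSpec",
    "CohortConfig",
    "EffectSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_effects",
    "generate_cohort",
    "make_healthy_unhealthy_mix",
]


@dataclass(frozen=True)
class VisitSpec:
    """A scheduled visit window: label, target age and age-jitter SD (days)."""

    name: str
    mean_age_days: float
    jitter_sd_days: float = 15.0


DEFAULT_VISITS = (
    VisitSpec("1m", 1 * DAYS_PER_MONTH),
    VisitSpec("3m", 3 * DAYS_PER_MONTH),
    VisitSpec("6m", 6 * DAYS_PER_MONTH),
    VisitSpec("12m", 12 * DAYS_PER_MONTH),
    VisitSpec("18m", 18 * DAYS_PER_MONTH),
)


@dataclass(frozen=True)
class CohortConfig:
    """Size and sampling design of a synthetic cohort.

    Defaults approximate the bundled study conditions: ~1/3 of children
    HIV-exposed-uninfected, a high-stunting population (~30 % LAZ <= -2 at
    18 months), five scheduled visits with 15-day jitter, ~10 % missed
    visits, ~20 % of children contributing only a single dataset (as happens
    when part of a cohort enters through an ancillary study), and moderately
    zero-inflated tables.
    """

    n_children: int = 100
    visits: Sequence[VisitSpec] = DEFAULT_VISITS
    n_species: int = 100
    n_pathways: int = 80
    frac_cheu: float = 0.3
    frac_hiv_positive: float = 0.01
    frac_hiv_unknown: float = 0.02
    frac_stunted: float = 0.3
    frac_single_sample: float = 0.2
    missing_visit_prob: float = 0.1
    zero_inflation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_children", "n_species", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "frac_cheu",
            "frac_hiv_positive",
            "frac_hiv_unknown",
            "frac_stunted",
            "frac_single_sample",
            "missing_visit_prob",
            "zero_inflation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.visits:
            raise ValueError("at least one visit required")


@dataclass
class EffectSpec:
    """Planted effects, all on the latent log-abundance scale.

    age_trend_features:
        feature -> slope per month of age.
    exposure_effects:
        (feature, exposure level) -> additive shift (e.g. reduced
        Bifidobacteria in CHEU).
    growth_effects:
        pathway feature -> coefficient on LAZ per SD of log abundance.
    whz_effects:
        pathway feature -> coefficient on WHZ per SD of log abundance.
    diversity_effect_cheu:
        flattening of the CHEU composition; positive values raise effective
        richness/evenness (the "over-diversification" signature).
    noise_sd:
        per-sample log-scale residual SD.
    """

    age_trend_features: Mapping[str, float] = field(default_factory=dict)
    exposure_effects: Mapping[tuple, float] = field(default_factory=dict)
    growth_effects: Mapping[str, float] = field(default_factory=dict)
    whz_effects: Mapping[str, float] = field(default_factory=dict)
    diversity_effect_cheu: float = 0.0
    noise_sd: float = 0.6


# A few recognizable names at the head of each feature list; the remainder
# are anonymous filler features.
_SPECIES_NAMES = [
    "Bifidobacterium_longum",
    "Bifidobacterium_bifidum",
    "Bifidobacterium_breve",
    "Escherichia_coli",
    "Bacteroides_fragilis",
    "Faecalibacterium_prausnitzii",
    "Prevotella_copri",
    "Roseburia_intestinalis",
    "Blautia_wexlerae",
    "Dorea_formicigenerans",
]

_PATHWAY_NAMES = [
    "THISYN-PWY_thiamine_diphosphate_biosynthesis",
    "PWY-841_purine_ribonucleotide_biosynthesis",
    "PWY-7357_thiamine_salvage",
    "RIBOSYN2-PWY_flavin_biosynthesis",
    "PWY-6700_queuosine_biosynthesis",
    "COBALSYN-PWY_cobalamin_salvage",
]


def _feature_names(prefix: str, named: list[str], n: int) -> list[str]:
    names = list(named[:n])
    names += [f"{prefix}_{i:04d}" for i in range(len(names), n)]
    return names


def default_effects(config: CohortConfig) -> EffectSpec:
    """Default planted structure: strong age succession, CHEU effects, and
    three growth-linked B-vitamin/nucleotide pathways."""
    species = _feature_names("Species", _SPECIES_NAMES, config.n_species)
    pathways = _feature_names("PWY", _PATHWAY_NAMES, config.n_pathways)
    age_trends: dict[str, float] = {}
    # Early Bifidobacterium dominance decaying with age.
    for sp in species[:3]:
        age_trends[sp] = -0.30
    # Late fermenters rising over the first 18 months.
    for sp in species[5:10]:
        age_trends[sp] = 0.28
    # Succession distributed over many taxa, and mostly colonization:
    # new species keep arriving over the first 18 months while a smaller
    # set of early (milk-adapted) taxa declines, so diversity rises with age.
    for sp in species[10:50]:
        age_trends[sp] = 0.15
    for sp in species[50:70]:
        age_trends[sp] = -0.10
    # Functional succession on pathways.
    for pw in pathways[:2]:
        age_trends[pw] = 0.22
    for pw in pathways[6:36]:
        age_trends[pw] = 0.12
    for pw in pathways[36:46]:
        age_trends[pw] = -0.08
    exposure = {
        (species[0], "CHEU"): -0.8,  # B. longum reduced in CHEU
        (species[1], "CHEU"): -0.8,  # B. bifidum reduced in CHEU
    }
    growth = {
        pathways[0]: 0.35,
        pathways[1]: 0.30,
        pathways[4]: -0.25,
    }
    whz = {
        pathways[1]: 0.25,
        pathways[3]: 0.20,
    }
    return EffectSpec(
        age_trend_features=age_trends,
        exposure_effects=exposure,
        growth_effects=growth,
        whz_effects=whz,
        diversity_effect_cheu=0.15,
    )


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a generated cohort."""

    planted_growth_features: dict
    planted_whz_features: dict
    age_trend_features: dict
    exposure_effects: dict
    diversity_effect_cheu: float
    latent_age_months: dict      # sample_id -> age signal used in generation
    child_trajectories: dict     # child_id -> {laz_intercept, laz_slope_per_month}
    laz_shift: float             # calibration shift applied to the LAZ scale

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticCohort:
    species: FeatureTable
    pathways: FeatureTable
    metadata: pd.DataFrame
    truth: SyntheticTruth


def _check_effects(effects: EffectSpec, species: list[str], pathways: list[str]) -> None:
    known = set(species) | set(pathways)
    for f in effects.age_trend_features:
        if f not in known:
            raise ValueError(f"age_trend_features references unknown feature {f!r}")
    for f, _exp in effects.exposure_effects:
        if f not in known:
            raise ValueError(f"exposure_effects references unknown feature {f!r}")
    for mapping, name in ((effects.growth_effects, "growth_effects"),
                          (effects.whz_effects, "whz_effects")):
        for f in mapping:
            if f not in known:
                raise ValueError(f"{name} references unknown feature {f!r}")


def _simulate_block(
    rng: np.random.Generator,
    child_rngs: list[np.random.Generator],
    names: list[str],
    samples: pd.DataFrame,
    effects: EffectSpec,
    config: CohortConfig,
    dominant_base: int,
) -> pd.DataFrame:
    """Latent log-normal abundances -> zero inflation -> compositional closure."""
    n_feat = len(names)
    base = rng.normal(0.0, 1.0, size=n_feat)
    # Dominant early colonizers start well above the field.
    base[:dominant_base] += 4.5
    # A rare tail, as in real profiler output: the last fifth of the filler
    # features sits far below the community (species-level thresholds drop
    # them; the far more permissive pathway threshold keeps them).
    n_rare = n_feat // 5
    if n_rare:
        base[n_feat - n_rare :] -= 7.0
    slopes = np.array([effects.age_trend_features.get(f, 0.0) for f in names])
    cheu_shift = np.array([effects.exposure_effects.get((f, "CHEU"), 0.0) for f in names])

    rows = np.empty((len(samples), n_feat))
    child_sd = 0.4  # per-child feature-level random effect SD
    child_effects: dict[str, np.ndarray] = {}
    for i, (_, s) in enumerate(samples.iterrows()):
        crng = child_rngs[s["child_index"]]
        cid = s["child_id"]
        if cid not in child_effects:
            child_effects[cid] = crng.normal(0.0, child_sd, size=n_feat)
        # Saturating age scale: assembly is rapid in the first months and
        # slows toward 18 months (keeps late communities from collapsing
        # onto the fastest-growing taxa).
        age_scale = 5.0 * np.log1p(s["age_months"])
        lat = (
            base
            + slopes * age_scale
            + child_effects[cid]
            + crng.normal(0.0, effects.noise_sd, size=n_feat)
        )
        if s["hiv_exposure"] == "CHEU":
            lat = lat + cheu_shift
            if effects.diversity_effect_cheu:
                # Flatten toward the mean: higher evenness/effective richness.
                lat = lat.mean() + (lat - lat.mean()) / (1.0 + effects.diversity_effect_cheu)
        abund = np.exp(lat)
        zero_mask = crng.random(n_feat) < config.zero_inflation
        abund[zero_mask] = 0.0
        total = abund.sum()
        if total == 0:  # pathological draw; keep one feature present
            abund[int(crng.integers(n_feat))] = 1.0
            total = 1.0
        remainder = crng.uniform(0.02, 0.15)  # unannotated fraction
        rows[i] = abund / total * (1.0 - remainder)
    return pd.DataFrame(rows, index=samples["sample_id"].to_numpy(), columns=names)


def generate_cohort(
    config: CohortConfig, effects: EffectSpec | None = None
) -> SyntheticCohort:
    """Generate species/pathway tables, metadata and ground truth.

    All randomness flows from ``config.seed`` through per-child sub-streams
    (spawned seed sequences), so regeneration is reproducible and stable
    under changes that do not touch a child's own draws.
    """
    species_names = _feature_names("Species", _SPECIES_NAMES, config.n_species)
    pathway_names = _feature_names("PWY", _PATHWAY_NAMES, config.n_pathways)
    if effects is None:
        effects = default_effects(config)
    _check_effects(effects, species_names, pathway_names)

    ss = np.random.SeedSequence(config.seed)
    cohort_ss, species_ss, pathway_ss, children_ss = ss.spawn(4)
    child_seeds = children_ss.spawn(config.n_children)
    # Independent per-child sub-streams for each purpose, so e.g. exposure
    # assignment and growth noise never share underlying random bits.
    child_streams = []
    for s in child_seeds:
        meta_s, sp_s, pw_s, growth_s = s.spawn(4)
        child_streams.append(
            {
                "meta": np.random.default_rng(meta_s),
                "species": np.random.default_rng(sp_s),
                "pathway": np.random.default_rng(pw_s),
                "growth": np.random.default_rng(growth_s),
            }
        )

    # --- children and visits -------------------------------------------
    records = []
    child_info = []
    for c in range(config.n_children):
        crng = child_streams[c]["meta"]
        cid = f"C{c + 1:04d}"
        u = crng.random()
        if u < config.frac_hiv_positive:
            hiv = "HIV_positive"
        elif u < config.frac_hiv_positive + config.frac_hiv_unknown:
            hiv = "HIV_unknown"
        elif u < config.frac_hiv_positive + config.frac_hiv_unknown + config.frac_cheu:
            hiv = "CHEU"
        else:
            hiv = "CHU"
        covars = {
            "epi_birthweight_kg": crng.normal(3.0, 0.45),
            "epi_maternal_height_cm": crng.normal(160.0, 6.0),
            "epi_maternal_muac_cm": crng.normal(26.0, 2.5),
            "epi_household_wealth": crng.normal(0.0, 1.0),
        }
        child = {
            "child_id": cid,
            "child_index": c,
            "hiv_exposure": hiv,
            "arm": ("SOC", "WASH", "IYCF", "WASH_IYCF")[int(crng.integers(4))],
            "ebf_3m": bool(crng.random() < 0.6),
            "delivery_csection": bool(crng.random() < 0.08),
            **covars,
        }
        child_info.append(child)
        # A fraction of children contribute a single dataset (e.g. enrolled
        # through an ancillary study): one uniformly chosen visit.
        single_visit = None
        if crng.random() < config.frac_single_sample:
            single_visit = config.visits[int(crng.integers(len(config.visits)))].name
        for v in config.visits:
            if single_visit is not None and v.name != single_visit:
                continue
            if single_visit is None and crng.random() < config.missing_visit_prob:
                continue
            age = max(1, int(round(crng.normal(v.mean_age_days, v.jitter_sd_days))))
            records.append(
                {
                    "sample_id": f"{cid}_{v.name}",
                    "visit": v.name,
                    "age_days": age,
                    "age_months": age / DAYS_PER_MONTH,
                    **child,
                }
            )
    samples = pd.DataFrame(records)

    # --- abundance tables ----------------------------------------------
    sp_rng = np.random.default_rng(species_ss)
    pw_rng = np.random.default_rng(pathway_ss)
    species_df = _simulate_block(
        sp_rng,
        [cs["species"] for cs in child_streams],
        species_names,
        samples,
        effects,
        config,
        dominant_base=3,
    )
    pathway_df = _simulate_block(
        pw_rng,
        [cs["pathway"] for cs in child_streams],
        pathway_names,
        samples,
        effects,
        config,
        dominant_base=0,
    )

    # --- growth outcomes ------------------------------------------------
    def planted_term(row_sample: str, mapping: Mapping[str, float]) -> float:
        total = 0.0
        for feat, coef in mapping.items():
            table = pathway_df if feat in pathway_df.columns else species_df
            col = table[feat]
            logged = np.log(col.to_numpy() + 1e-8)
            z = (np.log(col[row_sample] + 1e-8) - logged.mean()) / (logged.std() + 1e-12)
            total += coef * z
        return total

    traj = {}
    for child in child_info:
        crng = child_streams[child["child_index"]]["growth"]
        traj[child["child_id"]] = {
            "laz_intercept": float(crng.normal(-0.4, 0.55)),
            "laz_slope_per_month": float(crng.normal(-0.075, 0.03)),
            "whz_intercept": float(crng.normal(0.0, 0.5)),
        }

    laz_vals, whz_vals = [], []
    for _, s in samples.iterrows():
        t = traj[s["child_id"]]
        crng = child_streams[s["child_index"]]["growth"]
        laz = (
            t["laz_intercept"]
            + t["laz_slope_per_month"] * s["age_months"]
            + planted_term(s["sample_id"], effects.growth_effects)
            + 0.30 * (s["epi_birthweight_kg"] - 3.0) / 0.45
            + 0.15 * (s["epi_maternal_height_cm"] - 160.0) / 6.0
            + crng.normal(0.0, 0.3)
        )
        whz = (
            t["whz_intercept"]
            - 0.02 * s["age_months"]
            + planted_term(s["sample_id"], effects.whz_effects)
            + 0.20 * (s["epi_birthweight_kg"] - 3.0) / 0.45
            + crng.normal(0.0, 0.35)
        )
        laz_vals.append(laz)
        whz_vals.append(whz)
    samples["laz"] = laz_vals
    samples["whz"] = whz_vals

    # 18-month LAZ from the trajectory; calibrate the whole LAZ scale so the
    # stunting fraction at 18 months matches the configured target.
    laz_18_raw = {
        child["child_id"]: traj[child["child_id"]]["laz_intercept"]
        + traj[child["child_id"]]["laz_slope_per_month"] * 18.0
        for child in child_info
    }
    raw = np.array(list(laz_18_raw.values()))
    if config.frac_stunted <= 0:
        shift = 0.0
    else:
        shift = -2.0 - float(np.quantile(raw, config.frac_stunted))
    samples["laz"] = samples["laz"] + shift
    samples["laz_18m"] = samples["child_id"].map(
        {k: v + shift for k, v in laz_18_raw.items()}
    )

    meta = samples.drop(columns=["child_index", "age_months"])
    meta = validate_metadata(meta)

    truth = SyntheticTruth(
        planted_growth_features=dict(effects.growth_effects),
        planted_whz_features=dict(effects.whz_effects),
        age_trend_features=dict(effects.age_trend_features),
        exposure_effects={f"{f}|{e}": v for (f, e), v in effects.exposure_effects.items()},
        diversity_effect_cheu=effects.diversity_effect_cheu,
        latent_age_months={s: a for s, a in zip(samples["sample_id"], samples["age_months"])},
        child_trajectories={k: {**v} for k, v in traj.items()},
        laz_shift=shift,
    )
    species_table = FeatureTable(species_df, "species", {"source": "synthetic"})
    pathway_table = FeatureTable(pathway_df, "pathway", {"source": "synthetic"})
    return SyntheticCohort(species_table, pathway_table, meta, truth)


def make_healthy_unhealthy_mix(
    config: CohortConfig, effects: EffectSpec | None = None
) -> SyntheticCohort:
    """Cohort whose CHEU fraction and 18-month stunting fraction track the
    config targets (within binomial sampling error for exposure; by quantile
    calibration for stunting)."""
    cohort = generate_cohort(config, effects)
    children = cohort.metadata.drop_duplicates("child_id")
    n = len(children)
    n_cheu = int((children["hiv_exposure"] == "CHEU").sum())
    sd = np.sqrt(n * config.frac_cheu * (1 - config.frac_cheu))
    if abs(n_cheu - n * config.frac_cheu) > 4 * max(sd, 1.0):
        raise RuntimeError("CHEU fraction drifted beyond sampling error")
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write tables (TSV, percent units), metadata CSV and truth JSON."""
    from .feature_table import write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(cohort.species, outdir / "species.tsv")
    write_feature_table(cohort.pathways, outdir / "pathways.tsv")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    cohort.truth.to_json(outdir / "truth.json")
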