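"""End-to-end orchestration: YAML config, seeded runs, stage outputs, manifest.

A run executes (optionally) simulate → filter → diversity → differential
abundance → age model + MAZ → growth grid → ALE interpretation, writing each
stage's outputs under its own subdirectory of the run directory and a
manifest recording versions, seeds and input digests.  Stages never modify
one another's outputs; a stage failure halts the run with a stage-named
error, leaving earlier outputs in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .feature_table import (
    FilterSpec,
    PATHWAY_FILTER,
    SPECIES_FILTER,
    filter_features,
    load_feature_table,
    load_metadata,
    write_feature_table,
    write_filter_provenance,
)
from .diversity import alpha_diversity_frame, bray_curtis, pcoa, permanova
from .differential_abundance import results_to_frame, run_differential_abundance
from .growth import performance_frame, run_growth_grid
from .interpretation import ale
from .maturity import (
    SearchConfig,
    build_reference,
    compare_maturity,
    compute_maz_scores,
    fit_age_model,
    partition_cohort,
)
from .synthetic import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config", "StageError", "ALL_STAGES"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# -- config schema (unknown keys rejected) -----------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSettings(_Strict):
    min_rel_abund: float
    min_prevalence: float
    detection_threshold: float = 0.0

    def to_spec(self) -> FilterSpec:
        return FilterSpec(self.min_rel_abund, self.min_prevalence, self.detection_threshold)


class SimulateSettings(_Strict):
    n_children: int = 60
    n_species: int = 80
    n_pathways: int = 60
    frac_cheu: float = 0.3
    frac_stunted: float = 0.3
    missing_visit_prob: float = 0.1
    zero_inflation: float = 0.3


class InputSettings(_Strict):
    species_table: Optional[str] = None
    pathway_table: Optional[str] = None
    metadata: Optional[str] = None
    unit: Literal["percent", "fraction"] = "percent"


class SearchSettings(_Strict):
    n_iterations: int = 8
    stage1_folds: int = 10
    model_retention_quantile: float = 0.05
    importance_retention_fraction: float = 0.95
    importance_type: Literal["gain", "cover", "frequency"] = "gain"
    backend: Literal["gp", "random"] = "gp"
    n_initial: int = 5
    max_loocv_n: int = 60

    def to_config(self, seed: int) -> SearchConfig:
        return SearchConfig(
            n_iterations=self.n_iterations,
            stage1_folds=self.stage1_folds,
            model_retention_quantile=self.model_retention_quantile,
            importance_retention_fraction=self.importance_retention_fraction,
            importance_type=self.importance_type,
            backend=self.backend,
            n_initial=self.n_initial,
            max_loocv_n=self.max_loocv_n,
            seed=seed,
        )


class GrowthSettings(_Strict):
    outcomes: Sequence[str] = ("LAZ",)
    age_categories: Sequence[int] = (12,)
    strata: Sequence[str] = ("all",)
    feature_sets: Sequence[str] = ("microbiome_plus_epi",)
    feature_kinds: Sequence[str] = ("pathway",)
    min_n: int = 15


class DiffAbundSettings(_Strict):
    phenotype: str = "cheu"
    age_categories: Sequence[int] = (12,)
    feature_kind: Literal["species", "pathway"] = "species"


class RunConfig(_Strict):
    """Schema-validated run configuration (YAML)."""

    seed: int = 0
    simulate: Optional[SimulateSettings] = None
    inputs: Optional[InputSettings] = None
    species_filter: FilterSettings = FilterSettings(
        min_rel_abund=SPECIES_FILTER.min_rel_abund,
        min_prevalence=SPECIES_FILTER.min_prevalence,
    )
    pathway_filter: FilterSettings = FilterSettings(
        min_rel_abund=PATHWAY_FILTER.min_rel_abund,
        min_prevalence=PATHWAY_FILTER.min_prevalence,
    )
    search: SearchSettings = Field(default_factory=SearchSettings)
    growth: GrowthSettings = Field(default_factory=GrowthSettings)
    diffabund: DiffAbundSettings = Field(default_factory=DiffAbundSettings)
    age_model_kind: Literal["species", "pathway"] = "species"
    permanova_permutations: int = 999

    def validate_inputs(self) -> None:
        if self.simulate is None:
            ok = self.inputs is not None and all(
                getattr(self.inputs, f) for f in ("species_table", "pathway_table", "metadata")
            )
            if not ok:
                raise ValueError(
                    "config needs either a 'simulate' block or 'inputs' with "
                    "species_table, pathway_table and metadata paths"
                )


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**raw)
    cfg.validate_inputs()
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


ALL_STAGES = ("diversity", "diffabund", "maturity", "growth", "interpretation")


def run_pipeline(config: RunConfig, outdir, stages: Sequence[str] | None = None) -> Path:
    """Execute the pipeline into ``outdir``; returns the run directory.

    ``stages`` selects a subset of the analysis stages (input and filtering
    always run); ``interpretation`` implies ``growth``.  Default: all.
    """
    config.validate_inputs()
    if stages is None:
        stages = ALL_STAGES
    stages = set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "interpretation" in stages:
        stages.add("growth")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
    }

    def run_stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 2)})
        return out

    # -- input / simulate ---------------------------------------------------
    def _input():
        if config.simulate is not None:
            s = config.simulate
            cohort = generate_cohort(
                CohortConfig(
                    n_children=s.n_children,
                    n_species=s.n_species,
                    n_pathways=s.n_pathways,
                    frac_cheu=s.frac_cheu,
                    frac_stunted=s.frac_stunted,
                    missing_visit_prob=s.missing_visit_prob,
                    zero_inflation=s.zero_inflation,
                    seed=config.seed,
                )
            )
            write_cohort(cohort, outdir / "input")
            manifest["inputs"]["source"] = "simulate"
            return cohort.species, cohort.pathways, cohort.metadata
        inp = config.inputs
        species = load_feature_table(inp.species_table, "species", unit=inp.unit)
        pathways = load_feature_table(inp.pathway_table, "pathway", unit=inp.unit)
        meta = load_metadata(inp.metadata)
        for label, p in (
            ("species_table", inp.species_table),
            ("pathway_table", inp.pathway_table),
            ("metadata", inp.metadata),
        ):
            manifest["inputs"][label] = _digest(Path(p))
        return species, pathways, meta

    species, pathways, meta = run_stage("input", _input)

    def _filter():
        d = outdir / "filter"
        d.mkdir(exist_ok=True)
        sp = filter_features(species, config.species_filter.to_spec())
        pw = filter_features(pathways, config.pathway_filter.to_spec())
        write_feature_table(sp, d / "species_filtered.tsv")
        write_feature_table(pw, d / "pathways_filtered.tsv")
        write_filter_provenance(sp, d / "species_filter_provenance.json")
        write_filter_provenance(pw, d / "pathways_filter_provenance.json")
        return sp, pw

    sp_f, pw_f = run_stage("filter", _filter)

    def _diversity():
        d = outdir / "diversity"
        d.mkdir(exist_ok=True)
        alpha = alpha_diversity_frame(sp_f)
        alpha.to_csv(d / "alpha_diversity.csv", index_label="sample_id")
        dm = bray_curtis(sp_f)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            d / "bray_curtis.tsv", sep="\t"
        )
        ord_res = pcoa(dm, n_axes=4)
        ord_res.samples.to_csv(d / "pcoa_coordinates.csv")
        # exposure PERMANOVA per age category (CHEU vs CHU)
        rows = []
        m = meta.set_index("sample_id")
        for cat, sub in m.groupby("age_category"):
            sub = sub[sub["hiv_exposure"].isin(["CHEU", "CHU"])]
            ids = [s for s in sub.index if s in sp_f.data.index]
            if len(ids) < 6 or sub.loc[ids, "hiv_exposure"].nunique() < 2:
                continue
            sub_dm = dm.filter(ids)
            res = permanova(
                sub_dm,
                sub.loc[ids, "hiv_exposure"],
                n_permutations=config.permanova_permutations,
                seed=config.seed,
            )
            rows.append(
                {
                    "age_category": cat,
                    "r2": res.r2,
                    "f": res.f_stat,
                    "p": res.p_value,
                    "n": len(ids),
                }
            )
        pd.DataFrame(rows).to_csv(d / "permanova_exposure.csv", index=False)
        return alpha

    if "diversity" in stages:
        run_stage("diversity", _diversity)

    def _diffabund():
        d = outdir / "diffabund"
        d.mkdir(exist_ok=True)
        table = sp_f if config.diffabund.feature_kind == "species" else pw_f
        m = meta.copy()
        m["cheu"] = (m["hiv_exposure"] == "CHEU").astype(float)
        m = m[m["hiv_exposure"].isin(["CHEU", "CHU"])]
        for cat in config.diffabund.age_categories:
            sub = m[m["age_category"] == cat]
            if sub.empty:
                continue
            res = run_differential_abundance(
                table.subset_samples(
                    [s for s in sub["sample_id"] if s in table.data.index]
                ),
                sub,
                config.diffabund.phenotype,
            )
            results_to_frame(res).to_csv(d / f"diffabund_cat{cat}.csv", index=False)

    if "diffabund" in stages:
        run_stage("diffabund", _diffabund)

    def _maturity():
        d = outdir / "maturity"
        d.mkdir(exist_ok=True)
        table = sp_f if config.age_model_kind == "species" else pw_f
        part = partition_cohort(meta)
        res = fit_age_model(table, meta, part, config.search.to_config(config.seed))
        res.model.save(d / "age_model")
        res.predictions.to_csv(d / "predicted_ages.csv")
        json.dump(res.metrics, open(d / "age_model_metrics.json", "w"), indent=2, default=float)
        ref_preds = res.predictions.loc[
            res.predictions["set"] == "healthy_train", "predicted_age_months"
        ]
        reference = build_reference(ref_preds, meta)
        reference.table.to_csv(d / "maturity_reference.csv", index_label="visit")
        scores = compute_maz_scores(
            res.predictions["predicted_age_months"], meta, reference
        )
        scores.to_csv(d / "maz_scores.csv")
        try:
            comparison = compare_maturity(scores, meta)
            comparison.to_csv(d / "maz_exposure_regression.csv", index=False)
        except ValueError as exc:
            logger.info("maturity exposure comparison skipped: %s", exc)
        return res

    if "maturity" in stages:
        run_stage("maturity", _maturity)

    def _growth():
        d = outdir / "growth"
        d.mkdir(exist_ok=True)
        g = config.growth
        results = run_growth_grid(
            {"species": sp_f, "pathway": pw_f},
            meta,
            config.search.to_config(config.seed),
            outcomes=tuple(g.outcomes),
            age_categories=tuple(g.age_categories),
            strata=tuple(g.strata),
            feature_sets=tuple(g.feature_sets),
            feature_kinds=tuple(g.feature_kinds),
            min_n=g.min_n,
        )
        performance_frame(results).to_csv(d / "growth_performance.csv", index=False)
        for r in results:
            if r.status == "ok" and r.top_features is not None:
                r.top_features.to_csv(d / f"importance_{r.task.label()}.csv", index=False)
        return results

    growth_results = run_stage("growth", _growth) if "growth" in stages else []

    def _interpretation():
        d = outdir / "interpretation"
        d.mkdir(exist_ok=True)
        fitted = [r for r in growth_results if r.status == "ok" and r.model is not None]
        if not fitted:
            logger.info("no fitted growth model; ALE stage writes nothing")
            return
        best = max(fitted, key=lambda r: r.pseudo_r2)
        table = sp_f if best.task.feature_kind == "species" else pw_f
        m = meta.set_index("sample_id")
        sub = m[m["age_category"] == best.task.age_category]
        X = table.data.loc[table.data.index.intersection(sub.index)]
        if best.task.feature_set == "microbiome_plus_epi":
            from .growth import _one_hot_epi

            X = pd.concat([X, _one_hot_epi(sub.loc[X.index])], axis=1)
        top = best.top_features
        for feat in top["feature"].head(3):
            if feat not in X.columns:
                continue
            result = ale(best.model, X, feat, n_intervals=10)
            result.to_frame().to_csv(
                d / f"ale_{best.task.label()}_{_safe_name(feat)}.csv", index=False
            )

    if "interpretation" in stages:
        run_stage("interpretation", _interpretation)

    _write_manifest(outdir, manifest)
    return outdir


def _safe_name(s: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in str(s))[:80]


def _write_manifest(outdir: Path, manifest: dict) -> None:
    import numpy
    import sklearn
    import xgboost

    manifest["versions"] = {
        "numpy": numpy.__version__,
        "xgboost": xgboost.__version__,
        "scikit-learn": sklearn.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
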