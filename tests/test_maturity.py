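"""Cohort partition, staged selection mechanics, metrics, and MAZ scoring."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_regression_problem, tiny_search_config
from micromature.maturity import (
    MaturityReference,
    build_reference,
    compare_maturity,
    compute_maz,
    compute_maz_scores,
    mae,
    partition_cohort,
    pseudo_r2,
    three_stage_select,
    SelectedModel,
)


def _meta(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "child_id", "age_days", "visit", "hiv_exposure", "laz_18m"],
    )


class TestPartition:
    def test_three_rules(self):
        meta = _meta(
            [
                # CHU, LAZ>-2, 3 samples -> healthy train
                ("a1", "A", 30, "1m", "CHU", -1.0),
                ("a2", "A", 91, "3m", "CHU", -1.0),
                ("a3", "A", 183, "6m", "CHU", -1.0),
                # CHU, LAZ>-2, single sample -> healthy test
                ("b1", "B", 30, "1m", "CHU", -1.0),
                # CHEU -> unhealthy regardless of LAZ
                ("c1", "C", 30, "1m", "CHEU", 0.5),
                ("c2", "C", 91, "3m", "CHEU", 0.5),
                # CHU but stunted -> unhealthy
                ("d1", "D", 30, "1m", "CHU", -2.5),
            ]
        )
        part = partition_cohort(meta)
        assert sorted(part.healthy_train) == ["a1", "a2", "a3"]
        assert part.healthy_test == ["b1"]
        assert sorted(part.unhealthy) == ["c1", "c2", "d1"]

    def test_partition_covers_and_disjoint(self):
        from micromature.synthetic import CohortConfig, generate_cohort

        meta = generate_cohort(CohortConfig(n_children=40, n_species=10,
                                            n_pathways=5, seed=13)).metadata
        part = partition_cohort(meta)
        sets = [set(part.healthy_train), set(part.healthy_test), set(part.unhealthy)]
        assert sets[0] | sets[1] | sets[2] == set(meta["sample_id"])
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        # a child's samples never straddle partitions
        by_child = meta.groupby("child_id")["sample_id"].apply(set)
        for samples in by_child:
            assert sum(bool(samples & s) for s in sets) == 1

    def test_missing_age_excluded_and_missing_laz_unhealthy(self):
        meta = _meta(
            [
                ("a1", "A", np.nan, "1m", "CHU", -1.0),
                ("b1", "B", 30, "1m", "CHU", np.nan),
            ]
        )
        part = partition_cohort(meta)
        assert part.excluded_missing_age == ["a1"]
        assert part.unhealthy == ["b1"]


class TestMetrics:
    def test_perfect_prediction(self):
        assert pseudo_r2([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_zero(self):
        assert pseudo_r2([1, 2, 3], [2, 2, 2]) == 0.0

    def test_anticorrelated_negative(self):
        assert pseudo_r2([1, 2, 3], [3, 2, 1]) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2([2, 2, 2], [1, 2, 3])

    def test_mae_examples(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert mae([1, 2, 3], [2, 2, 2]) == pytest.approx(2 / 3)
        assert mae([3, 1, 2], [2, 2, 2]) == pytest.approx(2 / 3)


class TestThreeStageSelect:
    def test_identity_filters_drop_nothing(self):
        X, y, _ = make_regression_problem(n=30, p=8, seed=1)
        cfg = tiny_search_config(seed=1, n_iterations=3)
        cfg.model_retention_quantile = 1.0
        cfg.importance_retention_fraction = 1.0
        sel = three_stage_select(X, y, cfg)
        assert sorted(sel.retained_features) == sorted(X.columns)

    def test_stagewise_monotone_feature_subsets(self):
        X, y, _ = make_regression_problem(n=50, p=25, seed=2)
        sel = three_stage_select(X, y, tiny_search_config(seed=2))
        s1 = set(sel.stage_history[0]["retained_features"])
        s2 = set(sel.stage_history[1]["retained_features"])
        assert s2 <= s1
        assert set(sel.retained_features) == s2

    def test_planted_signal_retained_small(self):
        X, y, signal = make_regression_problem(n=60, p=30, n_signal=3, seed=3)
        sel = three_stage_select(X, y, tiny_search_config(seed=3, n_iterations=5))
        assert set(signal) <= set(sel.retained_features)
        assert sel.metrics["pseudo_r2"] > 0.5

    def test_constant_response_no_crash(self):
        X, _, _ = make_regression_problem(n=30, p=6, seed=4)
        sel = three_stage_select(X, np.full(30, 2.0), tiny_search_config(seed=4, n_iterations=3))
        assert sel.metrics["pseudo_r2"] <= 0

    def test_out_of_fold_discipline(self):
        # every training sample's prediction comes from a fold whose
        # training half excluded it
        X, y, _ = make_regression_problem(n=40, p=10, seed=5)
        sel = three_stage_select(X, y, tiny_search_config(seed=5, n_iterations=3))
        folds = sel.oof_fold_assignment
        assert folds.notna().all() and (folds >= 0).all()
        # refitting the final model on all data gives different (better)
        # in-sample predictions than the recorded out-of-fold ones
        insample = sel.model.predict(X[sel.retained_features])
        assert not np.allclose(insample, sel.oof_predictions.to_numpy())

    def test_seeded_reproducibility(self):
        X, y, _ = make_regression_problem(n=40, p=10, seed=6)
        a = three_stage_select(X, y, tiny_search_config(seed=6, n_iterations=3))
        b = three_stage_select(X, y, tiny_search_config(seed=6, n_iterations=3))
        assert a.final_hyperparameters == b.final_hyperparameters
        assert np.allclose(a.oof_predictions, b.oof_predictions)

    def test_too_few_samples_rejected(self):
        X, y, _ = make_regression_problem(n=5, p=4, seed=7)
        cfg = tiny_search_config(seed=7, folds=10)
        with pytest.raises(ValueError, match="folds"):
            three_stage_select(X, y, cfg)

    def test_save_load_round_trip(self, tmp_path):
        X, y, _ = make_regression_problem(n=30, p=6, seed=8)
        sel = three_stage_select(X, y, tiny_search_config(seed=8, n_iterations=3))
        sel.save(tmp_path / "m")
        loaded = SelectedModel.load(tmp_path / "m")
        assert loaded.retained_features == sel.retained_features
        assert np.allclose(loaded.predict(X), sel.predict(X))


class TestReferenceAndMaz:
    def _ref_meta(self):
        return pd.DataFrame(
            {
                "sample_id": ["r1", "r2", "r3", "q1"],
                "visit": ["6m", "6m", "6m", "12m"],
            }
        )

    def test_reference_median_and_sd(self):
        preds = pd.Series([10.0, 12.0, 14.0], index=["r1", "r2", "r3"])
        ref = build_reference(preds, self._ref_meta())
        assert ref.table.loc["6m", "median"] == 12.0
        assert ref.table.loc["6m", "sd"] == pytest.approx(2.0)

    def test_reference_invariant_to_order(self):
        meta = self._ref_meta()
        p1 = pd.Series([10.0, 12.0, 14.0], index=["r1", "r2", "r3"])
        p2 = p1.iloc[::-1]
        r1 = build_reference(p1, meta).table
        r2 = build_reference(p2, meta).table
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_visit_flagged(self):
        preds = pd.Series([5.0, 5.0], index=["r1", "r2"])
        with pytest.warns(UserWarning, match="unusable"):
            ref = build_reference(preds, self._ref_meta())
        assert not ref.table.loc["6m", "usable"]
        with pytest.warns(UserWarning):
            assert np.isnan(compute_maz(6.0, "6m", ref))

    def test_maz_values(self):
        preds = pd.Series([10.0, 12.0, 14.0], index=["r1", "r2", "r3"])
        ref = build_reference(preds, self._ref_meta())
        assert compute_maz(12.0, "6m", ref) == 0.0
        assert compute_maz(14.0, "6m", ref) == pytest.approx(1.0)

    def test_reference_set_maz_median_zero(self):
        rng = np.random.default_rng(10)
        ids = [f"r{i}" for i in range(30)]
        meta = pd.DataFrame(
            {"sample_id": ids, "visit": ["1m", "3m", "6m"] * 10}
        )
        preds = pd.Series(rng.uniform(1, 18, 30), index=ids)
        ref = build_reference(preds, meta)
        scores = compute_maz_scores(preds, meta, ref)
        med = scores.groupby("visit")["maz"].median()
        assert (med.abs() < 1e-9).all()


class TestCompareMaturity:
    def _scored_cohort(self, shift, seed, n=160):
        rng = np.random.default_rng(seed)
        cheu = rng.random(n) < 0.4
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "child_id": [f"c{i}" for i in range(n)],
                "age_days": rng.integers(150, 240, n),
                "age_category": 6,
                "visit": "6m",
                "hiv_exposure": np.where(cheu, "CHEU", "CHU"),
                "ebf_3m": rng.random(n) < 0.5,
                "delivery_csection": rng.random(n) < 0.1,
                "arm": rng.choice(["SOC", "WASH", "IYCF", "WASH_IYCF"], n),
            }
        )
        maz = rng.normal(0, 1, n) + shift * cheu
        scores = pd.DataFrame(
            {"maz": maz, "visit": "6m"}, index=pd.Index(meta["sample_id"], name="sample_id")
        )
        return scores, meta

    def test_null_p_uniform(self):
        hits = 0
        for seed in range(200):
            scores, meta = self._scored_cohort(0.0, 300 + seed, n=80)
            res = compare_maturity(scores, meta)
            hits += res["p"].iloc[0] <= 0.05
        assert 0.02 <= hits / 200 <= 0.09

    def test_planted_overmaturity_positive_beta(self):
        pos = 0
        for seed in range(20):
            scores, meta = self._scored_cohort(1.0, 600 + seed)
            res = compare_maturity(scores, meta)
            pos += res["beta"].iloc[0] > 0
        assert pos == 20

    def test_single_group_rejected(self):
        scores, meta = self._scored_cohort(0.0, 1)
        meta["hiv_exposure"] = "CHU"
        with pytest.raises(ValueError):
            compare_maturity(scores, meta)
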