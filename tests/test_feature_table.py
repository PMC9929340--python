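"""Feature-table parsing, filtering thresholds, and age-category binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from micromature.feature_table import (
    FeatureTable,
    FeatureTableError,
    FilterSpec,
    PATHWAY_FILTER,
    SPECIES_FILTER,
    assign_age_category,
    filter_features,
    load_feature_table,
    validate_metadata,
    write_feature_table,
)


def _write_tsv(path, text):
    path.write_text(text)
    return path


class TestLoad:
    def test_percent_units_become_fractions(self, tmp_path):
        p = _write_tsv(
            tmp_path / "t.tsv",
            "species_id\ts1\ts2\ts3\nA\t60\t60\t60\nB\t40\t40\t40\n",
        )
        t = load_feature_table(p, "species", unit="percent")
        assert t.data.shape == (3, 2)
        assert np.allclose(t.data["A"], 0.6)
        assert np.allclose(t.data["B"], 0.4)

    def test_duplicate_feature_row_named_in_error(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", "id\ts1\nA\t10\nA\t20\n")
        with pytest.raises(FeatureTableError, match="A"):
            load_feature_table(p, "species")

    def test_negative_value_named_in_error(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", "id\ts1\nA\t10\nB\t-1\n")
        with pytest.raises(FeatureTableError, match="B"):
            load_feature_table(p, "species")

    def test_ragged_row_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "t.tsv", "id\ts1\ts2\nA\t10\t20\nB\t5\n")
        with pytest.raises(FeatureTableError, match="B"):
            load_feature_table(p, "species")

    def test_round_trip_preserves_values(self, tmp_path, tiny_table):
        path = tmp_path / "rt.tsv"
        write_feature_table(tiny_table, path)
        back = load_feature_table(path, "species")
        assert np.allclose(
            back.data[tiny_table.data.columns].to_numpy(),
            tiny_table.data.to_numpy(),
            atol=1e-12,
        )


class TestInvariants:
    def test_row_sums_above_one_rejected(self):
        df = pd.DataFrame({"A": [0.7], "B": [0.4]}, index=["s1"])
        with pytest.raises(FeatureTableError, match="s1"):
            FeatureTable(df, "species")

    def test_unannotated_remainder_allowed(self):
        df = pd.DataFrame({"A": [0.3], "B": [0.4]}, index=["s1"])
        t = FeatureTable(df, "species")
        assert t.data.sum(axis=1).iloc[0] < 1


class TestFilter:
    def test_low_prevalence_species_dropped(self):
        # present in 4 of 100 samples: prevalence 4 % < 5 %
        data = pd.DataFrame(
            {"rare": [0.01] * 4 + [0.0] * 96, "common": [0.01] * 100},
            index=[f"s{i}" for i in range(100)],
        )
        out = filter_features(FeatureTable(data, "species"), SPECIES_FILTER)
        assert out.feature_ids == ["common"]
        assert out.provenance["filter"]["dropped_features"] == ["rare"]

    def test_low_abundance_species_dropped(self):
        # max abundance 0.05 % fails the > 0.1 % species threshold
        data = pd.DataFrame(
            {"faint": [0.0005] * 20, "common": [0.01] * 20},
            index=[f"s{i}" for i in range(20)],
        )
        out = filter_features(FeatureTable(data, "species"), SPECIES_FILTER)
        assert out.feature_ids == ["common"]

    def test_pathway_filter_is_permissive_on_abundance(self):
        data = pd.DataFrame(
            {"tiny": [1e-8] * 20, "zero": [0.0] * 20},
            index=[f"s{i}" for i in range(20)],
        )
        out = filter_features(FeatureTable(data, "pathway"), PATHWAY_FILTER)
        assert out.feature_ids == ["tiny"]

    def test_empty_feature_set_passes_through(self):
        t = FeatureTable(pd.DataFrame(index=["s1", "s2"]), "species")
        out = filter_features(t, SPECIES_FILTER)
        assert out.n_features == 0

    def test_idempotent_and_partitioning(self, tiny_table):
        spec = FilterSpec(min_rel_abund=0.2, min_prevalence=0.5)
        once = filter_features(tiny_table, spec)
        twice = filter_features(once, spec)
        pd.testing.assert_frame_equal(once.data, twice.data)
        dropped = set(once.provenance["filter"]["dropped_features"])
        assert dropped | set(once.feature_ids) == set(tiny_table.feature_ids)
        assert dropped.isdisjoint(once.feature_ids)

    def test_values_not_renormalized(self, tiny_table):
        spec = FilterSpec(min_rel_abund=0.2, min_prevalence=0.5)
        out = filter_features(tiny_table, spec)
        kept = out.feature_ids
        assert np.allclose(out.data.to_numpy(), tiny_table.data[kept].to_numpy())


class TestAgeCategories:
    @pytest.mark.parametrize(
        "days,expected",
        [
            (0, 1),
            (30, 1),
            (42, 1),       # 6 weeks inclusive
            (43, 2),
            (91, 2),       # just below 3 months (91.3125 d)
            (92, 3),
            (120, 3),
            (182, 3),
            (183, 6),
            (273, 6),
            (274, 12),
            (456, 12),
            (457, 18),
            (608, 18),     # just below the 20-month cap (608.75 d)
            (609, None),   # beyond 20 months: out of range
            (650, None),
        ],
    )
    def test_bin_edges(self, days, expected):
        assert assign_age_category(days) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_age_category(-1)

    @given(st.integers(min_value=0, max_value=608))
    @settings(max_examples=200, deadline=None)
    def test_total_and_monotone(self, days):
        cat = assign_age_category(days)
        assert cat in (1, 2, 3, 6, 12, 18)
        nxt = assign_age_category(days + 1)
        if nxt is not None:
            assert nxt >= cat


class TestMetadata:
    def _base(self):
        return pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "child_id": ["c1", "c1"],
                "age_days": [30, 95],
                "visit": ["1m", "3m"],
                "hiv_exposure": ["CHU", "CHU"],
                "arm": ["WASH_IYCF", "WASH_IYCF"],
            }
        )

    def test_derived_arm_indicators(self):
        m = validate_metadata(self._base())
        assert m["wash_arm"].all() and m["iycf_arm"].all()
        assert list(m["age_category"]) == [1, 3]

    def test_duplicate_child_visit_rejected(self):
        bad = self._base()
        bad.loc[1, "visit"] = "1m"
        with pytest.raises(ValueError, match="c1"):
            validate_metadata(bad)
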