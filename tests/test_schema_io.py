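"""Schema handling, cohort IO, visit bucketing, filtering, and encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trajgen import (ADASCOG11_COMPONENTS, CohortTable, Encoder, SchemaSet,
                     VariableSchema, bucket_visits, default_schema,
                     filter_patients, make_time_pairs, read_cohort, write_cohort)
from trajgen.cohort import CohortValidationError, assign_visit
from trajgen.schema import DAYS_PER_MONTH


class TestDefaultSchema:
    def test_has_44_variables_with_expected_composition(self):
        schema = default_schema()
        assert len(schema) == 44
        assert len(schema.by_category("ADAS")) == 12
        assert len(schema.by_category("MMSE")) == 5
        assert len(schema.by_category("laboratory")) == 14
        assert len(schema.by_category("clinical")) == 5
        assert len(schema.by_category("background")) == 8
        assert len(schema.dynamic) == 36
        assert len(schema.static) == 8
        # all cognitive components are dynamic ordinals
        for name in schema.by_category("ADAS") + schema.by_category("MMSE"):
            assert schema[name].value_type == "ordinal"
            assert schema[name].temporal == "dynamic"
        assert len(ADASCOG11_COMPONENTS) == 11
        assert "adas_delayed_word_recall" not in ADASCOG11_COMPONENTS

    def test_apoe_missingness_matches_declared_rate(self):
        assert default_schema()["apoe4_count"].missing_rate == pytest.approx(0.724)

    def test_yaml_round_trip(self, tmp_path):
        schema = default_schema()
        path = tmp_path / "schema.yaml"
        schema.to_yaml(str(path))
        loaded = SchemaSet.from_yaml(str(path))
        assert loaded.names == schema.names
        for name in schema.names:
            assert loaded[name] == schema[name]

    @pytest.mark.parametrize("kwargs", [
        dict(bounds=(0.5, 3)),              # non-integer ordinal bound
        dict(bounds=(3, 3)),                # empty range
    ])
    def test_invalid_ordinal_bounds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariableSchema("x", "ADAS", "ordinal", "dynamic", **kwargs)

    def test_value_validation(self):
        schema = default_schema()
        assert schema["sex"].check_value("1") == 1.0
        with pytest.raises(ValueError):
            schema["sex"].check_value(9)          # binary out of range
        with pytest.raises(ValueError):
            schema["adas_commands"].check_value(7)  # above ordinal bound
        assert schema["race"].check_value("white") == "white"
        with pytest.raises(ValueError):
            schema["race"].check_value("blue")


class TestCohortIO:
    def test_read_simple_file(self, tmp_path, small_schema):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,visit_month,variable,value\n"
                        "p1,0,score,2\np1,3,score,3\np1,6,score,4\n")
        cohort = read_cohort(str(path), small_schema)
        assert len(cohort) == 3
        assert cohort.patients == ["p1"]

    def test_out_of_bounds_value_rejected(self, tmp_path, small_schema):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,visit_month,variable,value\np1,0,sex,9\n")
        with pytest.raises(CohortValidationError):
            read_cohort(str(path), small_schema)

    def test_unknown_variable_rejected(self, tmp_path, small_schema):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,visit_month,variable,value\np1,0,bogus,1\n")
        with pytest.raises(CohortValidationError, match="bogus"):
            read_cohort(str(path), small_schema)

    def test_empty_value_becomes_missing(self, tmp_path, small_schema):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,visit_month,variable,value\n"
                        "p1,0,score,2\np1,3,score,\n")
        cohort = read_cohort(str(path), small_schema)
        assert len(cohort) == 1

    def test_write_read_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "out.csv"
        write_cohort(small_cohort, str(path))
        again = read_cohort(str(path), small_cohort.schema)
        assert again.equals(small_cohort)

    def test_duplicate_cells_rejected(self, small_schema):
        df = pd.DataFrame({"patient_id": ["p1", "p1"], "visit_month": [0, 0],
                           "variable": ["score", "score"], "value": [1.0, 2.0]})
        with pytest.raises(CohortValidationError, match="duplicate"):
            CohortTable(df, small_schema)


class TestBucketVisits:
    def test_window_assignment_oracle(self):
        # month-3 center is at day 3 * 365.25/12 = 91.3125
        assert assign_visit(100.0) == 3
        assert assign_visit(50.0) == 3        # inside (46.3125, 136.3125]
        assert assign_visit(46.0) is None     # between the two windows
        assert assign_visit(45.0) == 0
        assert assign_visit(-45.0) == 0
        center3 = 3 * DAYS_PER_MONTH
        assert assign_visit(center3 + 45.0) == 3   # boundary: earlier window
        assert assign_visit(center3 + 45.0001) is None

    def test_mean_aggregation_within_window(self, small_schema):
        raw = pd.DataFrame({"patient_id": ["p1", "p1"], "day": [85.0, 95.0],
                            "variable": ["score", "score"], "value": ["4", "6"]})
        cohort = bucket_visits(raw, small_schema)
        assert cohort.df.iloc[0]["value"] == 5.0
        assert cohort.df.iloc[0]["visit_month"] == 3

    def test_extremal_aggregation_rule(self, small_schema):
        raw = pd.DataFrame({"patient_id": ["p1"] * 2, "day": [85.0, 95.0],
                            "variable": ["score"] * 2, "value": ["4", "6"]})
        cohort = bucket_visits(raw, small_schema, aggregation={"score": "max"})
        assert cohort.df.iloc[0]["value"] == 6.0

    def test_static_variables_averaged_to_baseline(self, small_schema):
        raw = pd.DataFrame({"patient_id": ["p1"] * 3, "day": [0.0, 100.0, 400.0],
                            "variable": ["sex"] * 3, "value": ["1", "1", "1"]})
        cohort = bucket_visits(raw, small_schema)
        assert len(cohort) == 1
        assert cohort.df.iloc[0]["visit_month"] == 0

    @settings(max_examples=25, deadline=None)
    @given(days=st.lists(st.floats(min_value=0, max_value=600), min_size=1,
                         max_size=20))
    def test_each_record_assigned_to_at_most_one_window(self, days):
        for d in days:
            month = assign_visit(d)
            if month is not None:
                assert abs(d - month * DAYS_PER_MONTH) <= 45.0


class TestFilterPatients:
    @staticmethod
    def _cohort_with_components(present_15, present_18):
        schema = default_schema()
        rows = []
        for i, name in enumerate(ADASCOG11_COMPONENTS):
            if name in present_15:
                rows.append(("p1", 15, name, 1.0))
            if name in present_18:
                rows.append(("p1", 18, name, 1.0))
        df = pd.DataFrame(rows, columns=["patient_id", "visit_month",
                                         "variable", "value"])
        return CohortTable(df, schema, validate=False)

    def test_complete_month18_kept(self):
        cohort = self._cohort_with_components([], ADASCOG11_COMPONENTS)
        assert filter_patients(cohort).patients == ["p1"]

    def test_complete_month15_only_kept(self):
        cohort = self._cohort_with_components(ADASCOG11_COMPONENTS, [])
        assert filter_patients(cohort).patients == ["p1"]

    def test_incomplete_both_dropped(self):
        partial = ADASCOG11_COMPONENTS[:-1]
        cohort = self._cohort_with_components(partial, partial)
        assert filter_patients(cohort).patients == []

    def test_idempotent_and_subset(self):
        cohort = self._cohort_with_components(ADASCOG11_COMPONENTS, [])
        once = filter_patients(cohort)
        twice = filter_patients(once)
        assert set(once.patients) <= set(cohort.patients)
        assert once.patients == twice.patients


class TestEncoding:
    def test_round_trip_identity_on_observed_cells(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        dyn = small_cohort.schema.dynamic
        wide = small_cohort.wide(0, dyn)
        em = enc.encode_slab(wide, dyn)
        back = enc.decode_slab(em.X, dyn)
        back.index = wide.index
        for p in wide.index:
            for v in dyn:
                if pd.notna(wide.loc[p, v]):
                    assert float(back.loc[p, v]) == pytest.approx(
                        float(wide.loc[p, v]), abs=1e-9)

    def test_onehot_groups_sum_to_one_where_observed(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        em = enc.encode_slab(small_cohort.wide(0, ["site"]), ["site"])
        assert np.allclose(em.X.sum(axis=1), 1.0)
        assert em.mask.all()

    def test_standardized_training_mean_encodes_to_zero(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        m, s = enc.stats["marker"]
        wide = pd.DataFrame({"marker": [np.exp(m)]}, index=["x"])
        em = enc.encode_slab(wide, ["marker"])
        assert em.X[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_value_in_log_variable_rejected(self, small_schema):
        df = pd.DataFrame({"patient_id": ["p1"], "visit_month": [0],
                           "variable": ["marker"], "value": [-1.0]})
        cohort = CohortTable(df, small_schema, validate=False)
        with pytest.raises(CohortValidationError, match="non-positive"):
            Encoder(small_schema).fit(cohort)

    def test_missing_cells_masked_not_filled(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        wide = small_cohort.wide(3, ["marker"])
        em = enc.encode_slab(wide, ["marker"])
        missing_row = list(wide.index).index("p2")
        assert not em.mask[missing_row, 0]

    def test_time_pairs_counts_and_static_consistency(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        panel = enc.encode_panel(small_cohort)
        pairs_all = make_time_pairs(panel, keep="all")
        assert pairs_all.X.shape[0] == 3 * 6  # every consecutive pair kept
        # static block identical across one patient's vectors
        st_cols = slice(2 * panel.dynamic.shape[2], None)
        for i in range(3):
            rows = pairs_all.X[pairs_all.patient_idx == i, st_cols]
            assert np.allclose(rows, rows[0])
        # observed at months 0,3,6 -> dynamic observations only in pairs t=1,2,3
        pairs_any = make_time_pairs(panel, keep="any")
        assert pairs_any.X.shape[0] == 3 * 3

    def test_time_pairs_full_keeps_fully_observed_only(self, small_cohort):
        enc = Encoder(small_cohort.schema).fit(small_cohort)
        panel = enc.encode_panel(small_cohort)
        pairs = make_time_pairs(panel, keep="full")
        assert pairs.mask.all()
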