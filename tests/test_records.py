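"""Record I/O, CC-level assignment, exclusion criteria and derived features."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from drgcost import records as rec
from drgcost import synthetic as syn
from drgcost.errors import ConfigurationError, PipelineError


class TestReadWrite:
    def test_round_trip_preserves_fields(self, tmp_path, cc_setup):
        table, universe = cc_setup
        config = syn.default_config(n=50, seed=3)
        records = syn.generate_cohort(config, table, universe)
        path = tmp_path / "cohort.csv"
        rec.write_records(records, path)
        back = rec.read_records(path)
        assert not back.issues
        assert len(back.records) == 50
        for a, b in zip(records, back.records):
            assert a.record_id == b.record_id
            assert a.sex == b.sex and a.age == b.age and a.los == b.los
            assert a.secondary_dx == b.secondary_dx
            assert a.procedures == b.procedures
            assert a.total_cost == pytest.approx(b.total_cost, abs=0.005)
            for c in rec.COST_COMPONENTS:
                assert a.cost_components[c] == pytest.approx(
                    b.cost_components[c], abs=0.005
                )

    def test_blank_cost_flagged_others_parsed(self, tmp_path, record_factory):
        records = [record_factory(record_id=f"r{i}") for i in range(3)]
        path = tmp_path / "cohort.csv"
        rec.write_records(records, path)
        lines = path.read_text().splitlines()
        # blank out total_cost (13th data column) of the second row
        parts = lines[2].split(",")
        parts[12] = ""
        lines[2] = ",".join(parts)
        path.write_text("\n".join(lines) + "\n")
        result = rec.read_records(path)
        assert len(result.records) == 3
        assert [i.row for i in result.issues] == [1]
        assert result.records[1].missing_fields() == ["total_cost"]
        assert not result.records[0].missing_fields()

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,sex\nr1,male\n")
        with pytest.raises(ConfigurationError, match="missing required columns"):
            rec.read_records(path)

    def test_cc_table_round_trip(self, tmp_path, cc_setup):
        table, _ = cc_setup
        rec.write_cc_tables(table, tmp_path / "inc.csv", tmp_path / "exc.csv")
        back = rec.read_cc_tables(tmp_path / "inc.csv", tmp_path / "exc.csv")
        assert back == table


class TestAssignCCLevel:
    def test_mcc_when_secondary_on_list_and_primary_not_excluded(
        self, simple_cc_table, record_factory
    ):
        r = record_factory(primary_dx="P1", secondary_dx=("M1",))
        assert rec.assign_cc_level(r, simple_cc_table) is rec.CCLevel.MCC

    def test_empty_secondary_is_non_cc(self, simple_cc_table, record_factory):
        r = record_factory(secondary_dx=())
        assert rec.assign_cc_level(r, simple_cc_table) is rec.CCLevel.NON_CC

    def test_exclusion_voids_qualifying_code(self, simple_cc_table, record_factory):
        r = record_factory(primary_dx="P9", secondary_dx=("C1",))
        assert rec.assign_cc_level(r, simple_cc_table) is rec.CCLevel.NON_CC

    def test_mcc_precedence_over_cc(self, simple_cc_table, record_factory):
        r = record_factory(primary_dx="P1", secondary_dx=("C2", "M2"))
        assert rec.assign_cc_level(r, simple_cc_table) is rec.CCLevel.MCC

    @given(st.permutations(["C2", "M2", "ZZZ", "C1"]))
    def test_order_independent_over_secondary_dx(self, perm):
        table = rec.CCTable(
            mcc_codes=frozenset({"M2"}),
            cc_codes=frozenset({"C1", "C2"}),
            exclusion={"C1": frozenset({"P1"})},
        )
        from conftest import make_record

        r = make_record(primary_dx="P1", secondary_dx=tuple(perm))
        assert rec.assign_cc_level(r, table) is rec.CCLevel.MCC


class TestApplyExclusions:
    def _scheme(self):
        return frozenset({"P1", "OP1"})

    def test_los_over_cap_excluded(self, record_factory):
        records = [record_factory(record_id=f"r{i}", total_cost=1000.0 + i,
                                  cost_components={c: (1000.0 + i) / 8 for c in rec.COST_COMPONENTS})
                   for i in range(100)]
        records[7] = rec.InpatientRecord(
            **{**records[7].__dict__, "los": 61}
        )
        retained, log = rec.apply_exclusions(records, self._scheme(), trim=None)
        assert log.counts["los_gt_60"] == 1
        assert log.retained_n == 99

    def test_equal_costs_trim_removes_nothing(self, record_factory):
        records = [record_factory(record_id=f"r{i}") for i in range(40)]
        retained, log = rec.apply_exclusions(records, self._scheme())
        assert log.counts["cost_percentile_trim"] == 0
        assert log.retained_n == 40

    def test_first_violated_criterion_wins(self, record_factory):
        # missing cost AND los 99: counted under missing only
        r = record_factory(total_cost=None, los=99)
        others = [record_factory(record_id=f"r{i}") for i in range(10)]
        _, log = rec.apply_exclusions([r] + others, self._scheme(), trim=None)
        assert log.counts["missing_fields"] == 1
        assert log.counts["los_gt_60"] == 0

    def test_log_partitions_input(self, record_factory):
        records = (
            [record_factory(record_id=f"a{i}") for i in range(20)]
            + [record_factory(record_id="bad_code", primary_dx="NOPE")]
            + [record_factory(record_id="bad_los", los=77)]
            + [record_factory(record_id="bad_missing", sex=None)]
        )
        retained, log = rec.apply_exclusions(records, self._scheme(), trim=None)
        assert log.input_n == len(records)
        assert len(retained) + sum(log.counts.values()) == log.input_n
        log.check()

    def test_trim_is_monotone_in_bounds(self, cc_setup):
        table, universe = cc_setup
        records = syn.generate_cohort(syn.default_config(n=400, seed=9), table, universe)
        narrow, _ = rec.apply_exclusions(records, universe.scheme_codes, trim=(5, 95))
        wide, _ = rec.apply_exclusions(records, universe.scheme_codes, trim=(1, 99))
        narrow_ids = {r.record_id for r in narrow}
        wide_ids = {r.record_id for r in wide}
        assert narrow_ids <= wide_ids

    def test_engineered_raw_cohort_retains_5204(self):
        records, table, universe = syn.generate_study_cohort(seed=0)
        assert len(records) == 6214
        retained, log = rec.apply_exclusions(records, universe.scheme_codes)
        assert log.retained_n == 5204
        assert log.counts["missing_fields"] == 300
        assert log.counts["code_not_in_scheme"] == 301
        assert log.counts["los_gt_60"] == 301
        assert log.counts["cost_percentile_trim"] == 108

    def test_empty_survivor_set_is_pipeline_error(self, record_factory):
        records = [record_factory(primary_dx="NOPE")]
        with pytest.raises(PipelineError):
            rec.apply_exclusions(records, self._scheme())


class TestDeriveFeatures:
    @pytest.mark.parametrize(
        "age,expected",
        [(0, "0-17"), (17, "0-17"), (18, "18-65"), (65, "18-65"), (66, ">65"), (99, ">65")],
    )
    def test_age_band_boundaries(self, age, expected):
        assert rec.age_band_of(age) == expected

    def test_long_stay_boundary(self, simple_cc_table, record_factory):
        assert not rec.derive_features(
            record_factory(los=30), simple_cc_table
        ).long_stay
        feats = rec.derive_features(
            record_factory(age=66, los=31), simple_cc_table
        )
        assert feats.long_stay and feats.age_band == ">65"

    def test_cohort_frame_columns(self, default_cohort):
        frame = default_cohort["frame"]
        assert len(frame) == 5204
        assert set(frame.age_band) <= set(rec.AGE_BANDS)
        assert frame.long_stay.equals(frame.los > 30)
        assert set(frame.cc_level) <= {"MCC", "CC", "NonCC"}
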