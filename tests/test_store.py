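import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avipbk.store import (StoreParseError, StudyRecord, load_fixture_tables,
                          query, read_study_records, screen_outliers,
                          write_study_records)
from conftest import make_records

HEADER = ("study_id,species,sex,repro_state,parameter,value,unit,"
          "n_birds,dispersion_type,dispersion_value,citation")


def _write(tmp_path, rows, name="in.csv"):
    p = tmp_path / name
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadStudyRecords:
    def test_well_formed_file_parses_identically(self, tmp_path):
        rows = [
            "s1,chicken,female,laying,hematocrit_pct,27.5,%,10,SEM,0.9,refA",
            "s2,mallard,female,unknown,hematocrit_pct,45.0,%,,SD,2.0,refB",
            "s3,chicken,male,adult_nonlaying,hemoglobin_g_dL,10.1,g/dL,8,,,refC",
        ]
        recs = read_study_records(_write(tmp_path, rows))
        assert [r.study_id for r in recs] == ["s1", "s2", "s3"]
        assert recs[0].value == 27.5 and recs[0].dispersion.type == "SEM"
        assert recs[2].dispersion is None and recs[2].n_birds == 8

    def test_unit_alias_case_normalized(self, tmp_path):
        rows = ["s1,chicken,female,immature,albumin_g_dL,1.67,g/dl,,,,ref"]
        (rec,) = read_study_records(_write(tmp_path, rows))
        assert rec.unit == "g/dL"

    def test_na_value_skipped_and_logged(self, tmp_path, caplog):
        rows = [
            "s1,chicken,female,laying,hematocrit_pct,27.5,%,,,,ref",
            "s2,chicken,female,laying,hematocrit_pct,NA,%,,,,ref",
        ]
        with caplog.at_level(logging.WARNING):
            recs = read_study_records(_write(tmp_path, rows))
        assert len(recs) == 1
        assert any("row 3" in m for m in caplog.messages)

    def test_unknown_parameter_rejected_with_row_number(self, tmp_path):
        rows = ["s1,chicken,female,laying,blood_sparkle_index,1.0,%,,,,ref"]
        with pytest.raises(StoreParseError, match="row 2.*blood_sparkle_index"):
            read_study_records(_write(tmp_path, rows))

    def test_malformed_numeric_names_row_and_column(self, tmp_path):
        rows = ["s1,chicken,female,laying,hematocrit_pct,twenty,%,,,,ref"]
        with pytest.raises(StoreParseError, match="row 2.*value"):
            read_study_records(_write(tmp_path, rows))

    def test_missing_header_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("study_id,value\nx,1\n")
        with pytest.raises(StoreParseError, match="header"):
            read_study_records(p)

    def test_round_trip_value_and_unit_identical(self, tmp_path, fixture_records):
        out = tmp_path / "out.csv"
        write_study_records(fixture_records, out)
        back = read_study_records(out)
        assert len(back) == len(fixture_records)
        for a, b in zip(fixture_records, back):
            assert (a.value, a.unit, a.parameter, a.provenance) == \
                   (b.value, b.unit, b.parameter, b.provenance)


class TestScreenOutliers:
    def test_single_high_value_excluded_leave_one_out(self):
        recs = make_records([1.67, 1.50, 1.60, 1.55, 1.58, 4.8])
        kept, excluded = screen_outliers(recs, k=4)
        assert [r.value for r in kept] == [1.67, 1.50, 1.60, 1.55, 1.58]
        (e,) = excluded
        assert e["record"].value == 4.8
        assert e["loo_mean"] == pytest.approx(1.58, abs=1e-12)
        assert e["loo_sd"] == pytest.approx(0.06284, abs=1e-4)
        assert e["threshold"] == pytest.approx(1.8314, abs=1e-3)

    def test_zero_dispersion_identical_values_kept(self):
        kept, excluded = screen_outliers(make_records([1.0, 1.0, 1.0]))
        assert len(kept) == 3 and not excluded

    def test_reported_high_albumin_values_flagged_in_context(self):
        # seven immature-hen albumin studies around 1.67 g/dL plus the two
        # anomalously high published values 2.26 and 4.8 g/dL
        base = [1.67, 1.50, 1.60, 1.55, 1.58, 1.72, 1.63]
        kept, excluded = screen_outliers(make_records(base + [2.26, 4.8]), k=4)
        assert sorted(e["record"].value for e in excluded) == [2.26, 4.8]
        assert len(kept) == 7

    def test_fewer_than_three_records_never_screened(self):
        recs = make_records([1.0, 100.0])
        kept, excluded = screen_outliers(recs)
        assert len(kept) == 2 and not excluded

    def test_k_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            screen_outliers(make_records([1, 2, 3]), k=0)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3,
                              allow_nan=False), min_size=1, max_size=15))
    def test_partition_and_idempotence(self, values):
        recs = make_records(values)
        kept, excluded = screen_outliers(recs, k=4)
        # partition: kept u excluded == input, disjoint
        ids = sorted(r.study_id for r in kept) + \
            sorted(e["record"].study_id for e in excluded)
        assert sorted(ids) == sorted(r.study_id for r in recs)
        # idempotence: screening the kept set again excludes nothing
        kept2, excluded2 = screen_outliers(kept, k=4)
        assert not excluded2 and len(kept2) == len(kept)


class TestQuery:
    def test_laying_hen_hematocrit_fixture(self, fixture_records):
        hits = query(fixture_records, species="chicken", sex="female",
                     repro_state="laying", parameter="hematocrit_pct")
        assert hits and hits[0].value == 27.1
        assert hits[0].n_studies == 10  # aggregate of ten study means

    def test_empty_store_returns_empty(self):
        assert query([], species="chicken", parameter="hematocrit_pct") == []

    def test_unknown_state_is_not_a_wildcard(self, fixture_records):
        hits = query(fixture_records, species="mallard",
                     repro_state="unknown", parameter="hematocrit_pct")
        assert all(r.repro_state == "unknown" for r in hits)
        laying = query(fixture_records, species="mallard",
                       repro_state="laying", parameter="hematocrit_pct")
        assert laying == []  # the mallard Hct rows are labeled unknown

    def test_unknown_parameter_lists_known_keys(self, fixture_records):
        with pytest.raises(KeyError, match="known keys include"):
            query(fixture_records, parameter="sparkle_index")

    def test_invalid_enum_rejected(self, fixture_records):
        with pytest.raises(ValueError):
            query(fixture_records, sex="other")


def test_fixture_tables_all_load(fixture_records):
    tables = {r.provenance.split(";")[0] for r in fixture_records if r.provenance}
    assert {"table=tab1", "table=tab2", "table=tab3", "table=tab4",
            "table=tab5", "table=tab6", "table=tab7", "table=tab8",
            "table=results"} <= tables


def test_unknown_fixture_table_rejected():
    with pytest.raises(KeyError):
        load_fixture_tables(["tab99"])
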