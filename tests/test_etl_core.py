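"""Flat-file import, event-list construction and CDM population."""

import datetime as dt
from pathlib import Path

import pandas as pd
import pytest

from oncomop.etl_core import (
    build_eventliste,
    import_flat_files,
    parse_registry_date,
    populate_cdm,
    write_cdm,
)
from oncomop.metadata_mapper import build_source_to_standard, load_manual_table
from oncomop.synthetic_data import build_expressions
from oncomop.vocabulary_store import resolve_to_standard

from conftest import write_flat_file

DIAG_COLS = ["diagnosis_id", "patient_id", "diagnosis_date", "icd10gm",
             "icdo3_topography", "icdo3_morphology", "laterality",
             "tnm_t", "tnm_n", "tnm_m", "tnm_date"]
SURG_COLS = ["surgery_id", "patient_id", "diagnosis_id", "surgery_date", "ops_code"]
THER_COLS = ["therapy_id", "patient_id", "diagnosis_id", "therapy_start", "therapy_end"]
SIDE_COLS = ["side_effect_id", "therapy_id", "patient_id", "ctcae_code",
             "ctcae_grade", "onset_date"]
PAT_COLS = ["patient_id", "sex", "birth_year", "first_name", "last_name"]


def _diag(dx="D1", pid=1, date="2018-01-10", icd="C34.1", lat="R",
          t="", n="", m="", tnm_date=""):
    return {"diagnosis_id": dx, "patient_id": pid, "diagnosis_date": date,
            "icd10gm": icd, "icdo3_topography": "", "icdo3_morphology": "",
            "laterality": lat, "tnm_t": t, "tnm_n": n, "tnm_m": m,
            "tnm_date": tnm_date}


class TestDates:
    @pytest.mark.parametrize(
        "raw,expected,imputed",
        [
            ("2018-05-03", dt.date(2018, 5, 3), False),
            ("2018-05", dt.date(2018, 5, 15), True),
            ("2018", dt.date(2018, 7, 1), True),
            ("", None, False),
        ],
    )
    def test_partial_date_imputation(self, raw, expected, imputed):
        assert parse_registry_date(raw) == (expected, imputed)

    @pytest.mark.parametrize("raw", ["03.05.2018", "2018-13-01", "soon"])
    def test_bad_cells_raise(self, raw):
        with pytest.raises(ValueError):
            parse_registry_date(raw)


class TestImport:
    def test_empty_directory_empty_store(self, tmp_path):
        store = import_flat_files(tmp_path)
        assert store.n_files == 0 and store.n_rows == 0

    def test_file_and_row_counts(self, tmp_path):
        write_flat_file(tmp_path, "patient",
                        [{"patient_id": 1, "sex": "F", "birth_year": 1960,
                          "first_name": "a", "last_name": "b"}], PAT_COLS)
        write_flat_file(tmp_path, "diagnosis", [_diag(), _diag("D2", 1)], DIAG_COLS)
        store = import_flat_files(tmp_path)
        assert store.n_files == 2
        assert store.row_counts == {"patient": 1, "diagnosis": 2}

    def test_identifying_columns_dropped_at_import(self, tmp_path):
        write_flat_file(tmp_path, "patient",
                        [{"patient_id": 1, "sex": "F", "birth_year": 1960,
                          "first_name": "secret", "last_name": "secret"}], PAT_COLS)
        store = import_flat_files(tmp_path)
        assert "first_name" not in store.table("patient").columns
        assert "last_name" not in store.table("patient").columns

    def test_bad_date_cell_quarantines_row_with_diagnostic(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis",
                        [_diag(), _diag("D2", 2, date="not-a-date")], DIAG_COLS)
        store = import_flat_files(tmp_path)
        assert store.row_counts["diagnosis"] == 1
        assert len(store.quarantined) == 1
        assert "not-a-date" in store.quarantined[0].reason

    def test_unknown_file_is_skipped_with_warning(self, tmp_path):
        write_flat_file(tmp_path, "mystery", [{"x": 1}], ["x"])
        store = import_flat_files(tmp_path)
        assert store.skipped_files == ["mystery.csv"]

    def test_schema_mismatch_is_fatal_for_that_file_only(self, tmp_path):
        write_flat_file(tmp_path, "surgery", [{"surgery_id": "S1"}], ["surgery_id"])
        write_flat_file(tmp_path, "diagnosis", [_diag()], DIAG_COLS)
        store = import_flat_files(tmp_path)
        assert "surgery.csv" in store.failed_files
        assert store.row_counts == {"diagnosis": 1}


class TestEventListe:
    def test_diagnosis_and_dated_surgery_make_two_visits(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis", [_diag()], DIAG_COLS)
        write_flat_file(tmp_path, "surgery",
                        [{"surgery_id": "S1", "patient_id": 1, "diagnosis_id": "D1",
                          "surgery_date": "2018-02-01", "ops_code": "5-300.0"}], SURG_COLS)
        ev = build_eventliste(import_flat_files(tmp_path))
        assert ev.entries["visit_id"].nunique() == 2
        assert ev.n_excluded == 0

    def test_same_day_events_share_one_visit(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis", [_diag()], DIAG_COLS)
        write_flat_file(tmp_path, "surgery",
                        [{"surgery_id": "S1", "patient_id": 1, "diagnosis_id": "D1",
                          "surgery_date": "2018-01-10", "ops_code": "5-300.0"}], SURG_COLS)
        ev = build_eventliste(import_flat_files(tmp_path))
        assert ev.entries["visit_id"].nunique() == 1

    def test_undated_side_effect_inherits_therapy_start(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis", [_diag()], DIAG_COLS)
        write_flat_file(tmp_path, "systemic_therapy",
                        [{"therapy_id": "T1", "patient_id": 1, "diagnosis_id": "D1",
                          "therapy_start": "2018-03-01", "therapy_end": "2018-03-20"}],
                        THER_COLS)
        write_flat_file(tmp_path, "side_effect",
                        [{"side_effect_id": "SE1", "therapy_id": "T1", "patient_id": 1,
                          "ctcae_code": "ANE", "ctcae_grade": 2, "onset_date": ""}],
                        SIDE_COLS)
        ev = build_eventliste(import_flat_files(tmp_path))
        row = ev.entries[ev.entries["source_table"] == "side_effect"].iloc[0]
        assert row["event_date"] == dt.date(2018, 3, 1)

    def test_record_with_no_resolvable_date_is_excluded_and_counted(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis", [_diag(date="")], DIAG_COLS)
        ev = build_eventliste(import_flat_files(tmp_path))
        assert ev.entries.empty
        assert ev.n_excluded == 1

    def test_staging_uses_tnm_date_over_diagnosis_date(self, tmp_path):
        write_flat_file(tmp_path, "diagnosis",
                        [_diag(t="cT2", n="cN0", m="cM0", tnm_date="2018-02-20")],
                        DIAG_COLS)
        ev = build_eventliste(import_flat_files(tmp_path))
        staging = ev.entries[ev.entries["event_kind"] == "staging"].iloc[0]
        assert staging["event_date"] == dt.date(2018, 2, 20)
        assert ev.entries["visit_id"].nunique() == 2

    def test_visit_keys_are_unique_per_person_and_date(self, pipeline_result):
        e = pipeline_result.eventliste.entries
        per_visit = e.groupby("visit_id")[["person_id", "event_date"]].nunique()
        assert (per_visit <= 1).all().all()
        per_pair = e.groupby(["person_id", "event_date"])["visit_id"].nunique()
        assert (per_pair == 1).all()


def _mini_cdm(tmp_path, vocab_fixture, rows_by_file):
    src_dir = tmp_path / "src"
    cols = {
        "patient": PAT_COLS, "diagnosis": DIAG_COLS, "surgery": SURG_COLS,
        "systemic_therapy": THER_COLS, "side_effect": SIDE_COLS,
    }
    for name, rows in rows_by_file.items():
        write_flat_file(src_dir, name, rows, cols[name])
    source = import_flat_files(src_dir)
    store = vocab_fixture.store
    exprs = build_expressions(store)
    s2s = build_source_to_standard(exprs, store)
    manual = load_manual_table(vocab_fixture.manual_table_path)
    eventliste = build_eventliste(source)
    return populate_cdm(source, store, eventliste,
                        source_to_standard=s2s, source_to_concept=manual)


class TestPopulate:
    def test_empty_source_empty_cdm(self, tmp_path, vocab_fixture):
        cdm = _mini_cdm(tmp_path, vocab_fixture, {})
        for table in ("condition_occurrence", "procedure_occurrence", "observation"):
            assert cdm.table(table).empty

    def test_one_to_many_ops_code_expands_to_two_rows(self, tmp_path, vocab_fixture):
        store = vocab_fixture.store
        multi = next(
            c for c in store.concepts.values()
            if c.vocabulary_id == "OPS" and len(store._maps_to.get(c.concept_id, [])) > 1
        )
        cdm = _mini_cdm(tmp_path, vocab_fixture, {
            "patient": [{"patient_id": 1, "sex": "F", "birth_year": 1960,
                         "first_name": "", "last_name": ""}],
            "diagnosis": [_diag()],
            "surgery": [{"surgery_id": "S1", "patient_id": 1, "diagnosis_id": "D1",
                         "surgery_date": "2018-02-01", "ops_code": multi.concept_code}],
        })
        procedures = cdm.table("procedure_occurrence")
        assert len(procedures) == 2
        assert sorted(procedures["procedure_concept_id"]) == sorted(
            store._maps_to[multi.concept_id]
        )

    def test_unmappable_laterality_emits_concept_zero_row(self, tmp_path, vocab_fixture):
        cdm = _mini_cdm(tmp_path, vocab_fixture, {
            "patient": [{"patient_id": 1, "sex": "F", "birth_year": 1960,
                         "first_name": "", "last_name": ""}],
            "diagnosis": [_diag(lat="U")],
        })
        observations = cdm.table("observation")
        lat = observations[observations["source_item"] == "Laterality"]
        assert len(lat) == 1
        assert int(lat.iloc[0]["observation_concept_id"]) == 0
        assert lat.iloc[0]["observation_source_value"] == "U"

    def test_conservation_per_item(self, pipeline_result, vocab_fixture, registry_bundle):
        """Target rows = sum over source rows of max(1, n resolved)."""
        from oncomop.etl_core import _CONCEPT_COLUMN
        store = vocab_fixture.store
        ledger = registry_bundle.ledger_mappings
        emitted = {}
        for table, _ in _CONCEPT_COLUMN.items():
            frame = pipeline_result.cdm.table(table)
            for item, group in frame.groupby("source_item"):
                emitted[item] = emitted.get(item, 0) + len(group)
        for item, group in ledger.groupby("item"):
            if item == "Substances":
                continue  # free text: name-level, not code-level
            expected = sum(
                max(1, len([x for x in str(r.expected_concept_ids).split(";") if x]))
                for r in group.itertuples(index=False)
            )
            assert emitted[item] == expected, item

    def test_every_clinical_row_references_existing_visit_and_person(self, pipeline_result):
        from oncomop.etl_core import _CONCEPT_COLUMN
        cdm = pipeline_result.cdm
        visits = set(cdm.table("visit_occurrence")["visit_occurrence_id"])
        persons = set(cdm.table("person")["person_id"])
        assert set(cdm.table("visit_occurrence")["person_id"]) <= persons
        for table in _CONCEPT_COLUMN:
            frame = cdm.table(table)
            if frame.empty:
                continue
            assert set(frame["visit_occurrence_id"]) <= visits
            assert set(frame["person_id"]) <= persons


class TestIdempotence:
    def test_rerun_writes_byte_identical_dumps(self, pipeline_config, pipeline_result, tmp_path):
        from oncomop.cli import run_pipeline
        first = tmp_path / "a"
        second = tmp_path / "b"
        write_cdm(pipeline_result.cdm, first)
        write_cdm(run_pipeline(pipeline_config).cdm, second)
        names = sorted(p.name for p in first.glob("*.csv"))
        assert names == sorted(p.name for p in second.glob("*.csv"))
        for name in names:
            assert (first / name).read_bytes() == (second / name).read_bytes()
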