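"""Import registry flat files and populate OMOP CDM v5.4 tables.

The registry delivers patient-centric "best-of" flat files (one per
reporting theme: diagnosis, surgery, systemic therapy, ...).  OMOP is a
visit-centric model, but a cancer registry records no encounters — so
the ETL first derives the *event list*: every clinical record is given
a resolvable date (its own date, else the start of its parent therapy,
else the diagnosis date of its tumor) and all events of one person on
one day share a constructed visit.  The CDM population step then routes
each source item to its OMOP domain table, expanding one-to-many
concept resolutions into multiple target rows and emitting
``concept_id = 0`` rows (with the original code as source value) for
codes the vocabularies cannot represent.

The whole ETL is deterministic and idempotent: re-running on identical
inputs writes byte-identical CSV dumps.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .substance_normalizer import normalize_mention
from .vocabulary_store import VocabularyStore

__all__ = [
    "FLAT_FILE_SCHEMAS",
    "DEFAULT_ROUTING",
    "ItemRoute",
    "SourceStore",
    "EventList",
    "CdmStore",
    "import_flat_files",
    "build_eventliste",
    "populate_cdm",
    "write_cdm",
]

logger = logging.getLogger(__name__)

# OMOP type-concept for registry-sourced records and the generic
# outpatient-visit concept; universal vocabulary constants.
REGISTRY_TYPE_CONCEPT = 32879
OUTPATIENT_VISIT_CONCEPT = 9202
GENDER_CONCEPTS = {"M": 8507, "F": 8532}


@dataclass(frozen=True)
class FileSchema:
    """Declared layout of one flat file."""

    required: tuple[str, ...]
    date_columns: tuple[str, ...] = ()
    identifying: tuple[str, ...] = ()  # dropped at import (data protection)


# Best-of patient-centric flat files plus look-up tables.  Identifying
# fields (names) are declared so the importer can drop them on sight.
FLAT_FILE_SCHEMAS: dict[str, FileSchema] = {
    "patient": FileSchema(
        required=("patient_id", "sex", "birth_year"),
        identifying=("first_name", "last_name", "address", "registry_id"),
    ),
    "diagnosis": FileSchema(
        required=(
            "diagnosis_id",
            "patient_id",
            "diagnosis_date",
            "icd10gm",
            "icdo3_topography",
            "icdo3_morphology",
            "laterality",
            "tnm_t",
            "tnm_n",
            "tnm_m",
            "tnm_date",
        ),
        date_columns=("diagnosis_date", "tnm_date"),
    ),
    "surgery": FileSchema(
        required=("surgery_id", "patient_id", "diagnosis_id", "surgery_date", "ops_code"),
        date_columns=("surgery_date",),
    ),
    "systemic_therapy": FileSchema(
        required=("therapy_id", "patient_id", "diagnosis_id", "therapy_start", "therapy_end"),
        date_columns=("therapy_start", "therapy_end"),
    ),
    "substance": FileSchema(
        required=(
            "substance_id",
            "therapy_id",
            "patient_id",
            "substance_text",
            "administration_date",
        ),
        date_columns=("administration_date",),
    ),
    "radiation": FileSchema(
        required=("radiation_id", "patient_id", "diagnosis_id", "radiation_start", "radiation_type"),
        date_columns=("radiation_start",),
    ),
    "follow_up": FileSchema(
        required=("follow_up_id", "patient_id", "diagnosis_id", "assessment_date", "remission_status"),
        date_columns=("assessment_date",),
    ),
    "side_effect": FileSchema(
        required=(
            "side_effect_id",
            "therapy_id",
            "patient_id",
            "ctcae_code",
            "ctcae_grade",
            "onset_date",
        ),
        date_columns=("onset_date",),
    ),
    "death": FileSchema(
        required=("patient_id", "death_date"),
        date_columns=("death_date",),
    ),
    "regimen_ingredients": FileSchema(
        required=("regimen_concept_id", "ingredient_concept_id"),
    ),
}


@dataclass(frozen=True)
class QuarantinedRow:
    file: str
    row: int
    reason: str


@dataclass
class SourceStore:
    """Typed source tables loaded from one flat-file directory."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    quarantined: list[QuarantinedRow] = field(default_factory=list)
    skipped_files: list[str] = field(default_factory=list)
    failed_files: dict[str, str] = field(default_factory=dict)

    @property
    def n_files(self) -> int:
        return len(self.tables)

    @property
    def n_rows(self) -> int:
        return sum(self.row_counts.values())

    def table(self, name: str) -> pd.DataFrame:
        if name in self.tables:
            return self.tables[name]
        schema = FLAT_FILE_SCHEMAS.get(name)
        cols = list(schema.required) if schema else []
        return pd.DataFrame(columns=cols)


def parse_registry_date(raw: object) -> tuple[dt.date | None, bool]:
    """Parse an ISO-ish registry date cell, imputing partial dates.

    Registries commonly report year-only or year-month dates.  To keep
    events orderable these are imputed to mid-period — July 1 for a
    bare year, day 15 for a year-month — and flagged.  Returns
    ``(date, imputed)``; a blank cell yields ``(None, False)``; an
    unparseable cell raises ``ValueError``.
    """
    s = "" if raw is None else str(raw).strip()
    if not s or s.lower() in ("nan", "none"):
        return None, False
    parts = s.split("-")
    try:
        if len(parts) == 1:
            return dt.date(int(parts[0]), 7, 1), True
        if len(parts) == 2:
            return dt.date(int(parts[0]), int(parts[1]), 15), True
        if len(parts) == 3:
            return dt.date(int(parts[0]), int(parts[1]), int(parts[2])), False
    except ValueError as exc:
        raise ValueError(f"bad date cell {s!r}: {exc}") from None
    raise ValueError(f"bad date cell {s!r}")


def import_flat_files(directory: str | Path, delimiter: str = ",") -> SourceStore:
    """Load every recognized flat file under *directory*.

    Files whose stem is not a declared schema are skipped with a
    warning; a file whose header misses required columns fails (for
    that file only); a row with an unparseable date cell is quarantined
    with a diagnostic and the load continues.  Date columns are parsed
    in place to ``datetime.date`` (or None) with a companion
    ``<col>_imputed`` flag; declared identifying columns are dropped.
    """
    directory = Path(directory)
    store = SourceStore()
    for path in sorted(directory.glob("*.csv")):
        stem = path.stem
        if stem not in FLAT_FILE_SCHEMAS:
            logger.warning("skipping unknown flat file %s", path.name)
            store.skipped_files.append(path.name)
            continue
        schema = FLAT_FILE_SCHEMAS[stem]
        frame = pd.read_csv(
            path, sep=delimiter, dtype=str, keep_default_na=False, decimal=","
        )
        missing = [c for c in schema.required if c not in frame.columns]
        if missing:
            store.failed_files[path.name] = f"missing columns: {missing}"
            logger.error("schema mismatch in %s: missing %s", path.name, missing)
            continue
        frame = frame.drop(columns=[c for c in schema.identifying if c in frame.columns])

        keep = []
        parsed: dict[str, list] = {c: [] for c in schema.date_columns}
        imputed: dict[str, list] = {c: [] for c in schema.date_columns}
        for i, row in enumerate(frame.itertuples(index=False)):
            ok = True
            values = row._asdict()
            cells: dict[str, tuple[dt.date | None, bool]] = {}
            for col in schema.date_columns:
                try:
                    cells[col] = parse_registry_date(values[col])
                except ValueError as exc:
                    store.quarantined.append(QuarantinedRow(path.name, i, str(exc)))
                    ok = False
                    break
            if not ok:
                continue
            keep.append(i)
            for col in schema.date_columns:
                parsed[col].append(cells[col][0])
                imputed[col].append(cells[col][1])
        frame = frame.iloc[keep].reset_index(drop=True)
        for col in schema.date_columns:
            frame[col] = pd.Series(parsed[col], dtype=object)
            frame[f"{col}_imputed"] = imputed[col]
        store.tables[stem] = frame
        store.row_counts[stem] = len(frame)
        logger.info("loaded %s: %d rows", path.name, len(frame))
    return store


# ---------------------------------------------------------------------------
# Event list (event → visit assignment)
# ---------------------------------------------------------------------------

EVENTLISTE_COLUMNS = [
    "person_id",
    "event_kind",
    "source_table",
    "source_row_id",
    "event_date",
    "date_imputed",
    "visit_id",
]


@dataclass
class EventList:
    """Dated clinical events with their constructed visits."""

    entries: pd.DataFrame  # EVENTLISTE_COLUMNS
    n_excluded: int = 0
    excluded: list[tuple[str, str, str]] = field(default_factory=list)

    def visit_of(self, source_table: str, source_row_id: str, event_kind: str | None = None):
        e = self.entries
        mask = (e["source_table"] == source_table) & (e["source_row_id"] == source_row_id)
        if event_kind is not None:
            mask &= e["event_kind"] == event_kind
        hit = e[mask]
        if hit.empty:
            return None
        return hit.iloc[0]


def build_eventliste(source: SourceStore) -> EventList:
    """Date every clinical record and assign it to a visit.

    Date resolution chain per record: its own date → the start date of
    its parent systemic therapy → the diagnosis date of its tumor.
    Records with no resolvable date are excluded and counted.  Visits
    are one per distinct (person, date), keys assigned in (person,
    date) order starting at 1.
    """
    diagnosis = source.table("diagnosis")
    therapy = source.table("systemic_therapy")

    dx_date: dict[str, tuple[dt.date | None, bool]] = {}
    dx_person: dict[str, str] = {}
    for row in diagnosis.itertuples(index=False):
        dx_date[row.diagnosis_id] = (row.diagnosis_date, bool(row.diagnosis_date_imputed))
        dx_person[row.diagnosis_id] = row.patient_id
    th_date: dict[str, tuple[dt.date | None, bool]] = {}
    th_dx: dict[str, str] = {}
    for row in therapy.itertuples(index=False):
        th_date[row.therapy_id] = (row.therapy_start, bool(row.therapy_start_imputed))
        th_dx[row.therapy_id] = row.diagnosis_id

    def chain(own: tuple[dt.date | None, bool], therapy_id: str | None, diagnosis_id: str | None):
        if own[0] is not None:
            return own
        if therapy_id is not None and th_date.get(therapy_id, (None, False))[0] is not None:
            return th_date[therapy_id]
        if therapy_id is not None and diagnosis_id is None:
            diagnosis_id = th_dx.get(therapy_id)
        if diagnosis_id is not None and dx_date.get(diagnosis_id, (None, False))[0] is not None:
            return dx_date[diagnosis_id]
        return (None, False)

    rows: list[dict] = []
    excluded: list[tuple[str, str, str]] = []

    def emit(person, kind, table, row_id, resolved):
        date, imputed = resolved
        if date is None:
            excluded.append((table, str(row_id), kind))
            return
        rows.append(
            {
                "person_id": int(person),
                "event_kind": kind,
                "source_table": table,
                "source_row_id": str(row_id),
                "event_date": date,
                "date_imputed": imputed,
            }
        )

    for row in diagnosis.itertuples(index=False):
        emit(row.patient_id, "diagnosis", "diagnosis", row.diagnosis_id,
             (row.diagnosis_date, bool(row.diagnosis_date_imputed)))
        if any(str(v).strip() for v in (row.tnm_t, row.tnm_n, row.tnm_m)):
            own = (row.tnm_date, bool(row.tnm_date_imputed))
            emit(row.patient_id, "staging", "diagnosis", row.diagnosis_id,
                 chain(own, None, row.diagnosis_id))
    for row in source.table("surgery").itertuples(index=False):
        emit(row.patient_id, "surgery", "surgery", row.surgery_id,
             chain((row.surgery_date, bool(row.surgery_date_imputed)), None, row.diagnosis_id))
    for row in source.table("substance").itertuples(index=False):
        emit(row.patient_id, "systemic therapy", "substance", row.substance_id,
             chain((row.administration_date, bool(row.administration_date_imputed)),
                   row.therapy_id, None))
    for row in source.table("radiation").itertuples(index=False):
        emit(row.patient_id, "radiation", "radiation", row.radiation_id,
             chain((row.radiation_start, bool(row.radiation_start_imputed)), None, row.diagnosis_id))
    for row in source.table("follow_up").itertuples(index=False):
        emit(row.patient_id, "follow-up", "follow_up", row.follow_up_id,
             chain((row.assessment_date, bool(row.assessment_date_imputed)), None, row.diagnosis_id))
    for row in source.table("side_effect").itertuples(index=False):
        emit(row.patient_id, "side effect", "side_effect", row.side_effect_id,
             chain((row.onset_date, bool(row.onset_date_imputed)), row.therapy_id, None))
    for row in source.table("death").itertuples(index=False):
        emit(row.patient_id, "death", "death", row.patient_id,
             (row.death_date, bool(row.death_date_imputed)))

    entries = pd.DataFrame(rows, columns=EVENTLISTE_COLUMNS[:-1])
    if entries.empty:
        entries["visit_id"] = pd.Series(dtype=int)
        return EventList(entries=entries[EVENTLISTE_COLUMNS], n_excluded=len(excluded), excluded=excluded)

    visits = (
        entries[["person_id", "event_date"]]
        .drop_duplicates()
        .sort_values(["person_id", "event_date"])
        .reset_index(drop=True)
    )
    visits["visit_id"] = visits.index + 1
    entries = entries.merge(visits, on=["person_id", "event_date"], how="left")
    entries = entries.sort_values(
        ["person_id", "event_date", "source_table", "source_row_id", "event_kind"]
    ).reset_index(drop=True)
    return EventList(entries=entries[EVENTLISTE_COLUMNS], n_excluded=len(excluded), excluded=excluded)


# ---------------------------------------------------------------------------
# CDM population
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemRoute:
    """How one oBDS item travels into the CDM."""

    item: str
    source_table: str
    column: str
    vocabulary_id: str  # "" for free-text items handled specially
    domain_table: str
    event_kind: str


DEFAULT_ROUTING: tuple[ItemRoute, ...] = (
    ItemRoute("ICD-10-GM", "diagnosis", "icd10gm", "ICD10GM", "condition_occurrence", "diagnosis"),
    ItemRoute("Topography ICDO3", "diagnosis", "icdo3_topography", "ICDO3", "measurement", "diagnosis"),
    ItemRoute("Morphology ICDO3", "diagnosis", "icdo3_morphology", "ICDO3", "observation", "diagnosis"),
    ItemRoute("Laterality", "diagnosis", "laterality", "Cancer Modifier", "observation", "diagnosis"),
    ItemRoute("TNM-T", "diagnosis", "tnm_t", "TNM", "observation", "staging"),
    ItemRoute("TNM-N", "diagnosis", "tnm_n", "TNM", "observation", "staging"),
    ItemRoute("TNM-M", "diagnosis", "tnm_m", "TNM", "observation", "staging"),
    ItemRoute("OPS", "surgery", "ops_code", "OPS", "procedure_occurrence", "surgery"),
    ItemRoute("Substances", "substance", "substance_text", "", "drug_exposure", "systemic therapy"),
    ItemRoute("Radiation type", "radiation", "radiation_type", "OBDS-RADIATION", "procedure_occurrence", "radiation"),
    ItemRoute("Remission status", "follow_up", "remission_status", "OBDS-FOLLOWUP", "observation", "follow-up"),
    ItemRoute("CTCAE", "side_effect", "ctcae_code", "CTCAE", "condition_occurrence", "side effect"),
)

CDM_COLUMNS: dict[str, list[str]] = {
    "person": ["person_id", "gender_concept_id", "year_of_birth", "person_source_value"],
    "death": ["person_id", "death_date", "death_type_concept_id"],
    "visit_occurrence": [
        "visit_occurrence_id",
        "person_id",
        "visit_concept_id",
        "visit_start_date",
        "visit_end_date",
        "visit_type_concept_id",
    ],
    "condition_occurrence": [
        "condition_occurrence_id",
        "person_id",
        "condition_concept_id",
        "condition_start_date",
        "condition_type_concept_id",
        "visit_occurrence_id",
        "condition_source_value",
    ],
    "drug_exposure": [
        "drug_exposure_id",
        "person_id",
        "drug_concept_id",
        "drug_exposure_start_date",
        "drug_exposure_end_date",
        "drug_type_concept_id",
        "visit_occurrence_id",
        "drug_source_value",
    ],
    "procedure_occurrence": [
        "procedure_occurrence_id",
        "person_id",
        "procedure_concept_id",
        "procedure_date",
        "procedure_type_concept_id",
        "visit_occurrence_id",
        "procedure_source_value",
    ],
    "measurement": [
        "measurement_id",
        "person_id",
        "measurement_concept_id",
        "measurement_date",
        "measurement_type_concept_id",
        "visit_occurrence_id",
        "measurement_source_value",
    ],
    "observation": [
        "observation_id",
        "person_id",
        "observation_concept_id",
        "observation_date",
        "observation_type_concept_id",
        "visit_occurrence_id",
        "observation_source_value",
    ],
    "device_exposure": [
        "device_exposure_id",
        "person_id",
        "device_concept_id",
        "device_exposure_start_date",
        "device_type_concept_id",
        "visit_occurrence_id",
        "device_source_value",
    ],
}

_ID_COLUMN = {t: cols[0] for t, cols in CDM_COLUMNS.items()}
_CONCEPT_COLUMN = {
    "condition_occurrence": "condition_concept_id",
    "drug_exposure": "drug_concept_id",
    "procedure_occurrence": "procedure_concept_id",
    "measurement": "measurement_concept_id",
    "observation": "observation_concept_id",
    "device_exposure": "device_concept_id",
}
_DATE_COLUMN = {
    "condition_occurrence": "condition_start_date",
    "drug_exposure": "drug_exposure_start_date",
    "procedure_occurrence": "procedure_date",
    "measurement": "measurement_date",
    "observation": "observation_date",
    "device_exposure": "device_exposure_start_date",
}
_TYPE_COLUMN = {
    "condition_occurrence": "condition_type_concept_id",
    "drug_exposure": "drug_type_concept_id",
    "procedure_occurrence": "procedure_type_concept_id",
    "measurement": "measurement_type_concept_id",
    "observation": "observation_type_concept_id",
    "device_exposure": "device_type_concept_id",
}
_SOURCE_COLUMN = {
    "condition_occurrence": "condition_source_value",
    "drug_exposure": "drug_source_value",
    "procedure_occurrence": "procedure_source_value",
    "measurement": "measurement_source_value",
    "observation": "observation_source_value",
    "device_exposure": "device_source_value",
}

# provenance helpers kept in memory, stripped by write_cdm
HELPER_COLUMNS = ["source_item", "source_table", "source_row_id", "source_tumor_id"]


@dataclass
class CdmStore:
    """In-memory OMOP CDM v5.4 table set (clinical tables as frames)."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        if name in self.tables:
            return self.tables[name]
        return pd.DataFrame(columns=CDM_COLUMNS.get(name, []) + HELPER_COLUMNS)

    @property
    def row_counts(self) -> dict[str, int]:
        return {name: len(t) for name, t in sorted(self.tables.items())}


def _mapping_index(table: pd.DataFrame | None, code_col: str, vocab_col: str, target_col: str):
    index: dict[tuple[str, str], list[int]] = {}
    if table is None or table.empty:
        return index
    for row in table.itertuples(index=False):
        target = int(getattr(row, target_col))
        if target == 0:
            continue
        key = (str(getattr(row, vocab_col)), str(getattr(row, code_col)))
        bucket = index.setdefault(key, [])
        if target not in bucket:
            bucket.append(target)
    return {k: sorted(v) for k, v in index.items()}


def populate_cdm(
    source: SourceStore,
    store: VocabularyStore,
    eventliste: EventList,
    source_to_standard: pd.DataFrame | None = None,
    source_to_concept: pd.DataFrame | None = None,
    routing: Sequence[ItemRoute] = DEFAULT_ROUTING,
    substance_rules: list[tuple[str, str]] | None = None,
    type_concept: int = REGISTRY_TYPE_CONCEPT,
) -> CdmStore:
    """Populate the CDM table set from source tables + look-up tables.

    Automatic mappings (source_to_standard) win over manual ones
    (source_to_concept); a code in neither emits one row with
    ``concept_id = 0``.  One-to-many resolutions expand: each source
    row emits ``max(1, n_resolved)`` target rows.  Free-text substance
    fields are cleaned and matched by name instead of code.
    """
    for route in routing:
        if route.domain_table not in CDM_COLUMNS:
            raise ValueError(
                f"item {route.item!r} routes to undeclared domain table "
                f"{route.domain_table!r}"
            )

    auto = _mapping_index(
        source_to_standard, "source_code", "source_vocabulary_id", "target_concept_id"
    )
    manual = _mapping_index(
        source_to_concept, "source_code", "source_vocabulary_id", "target_concept_id"
    )

    entries = eventliste.entries
    visit_lookup: dict[tuple[str, str, str], tuple[int, dt.date]] = {}
    for row in entries.itertuples(index=False):
        visit_lookup[(row.source_table, row.source_row_id, row.event_kind)] = (
            int(row.visit_id),
            row.event_date,
        )

    cdm = CdmStore()

    # person / death from patient master data (identifying fields were
    # already dropped at import)
    patients = source.table("patient")
    person_rows = []
    for row in patients.itertuples(index=False):
        person_rows.append(
            {
                "person_id": int(row.patient_id),
                "gender_concept_id": GENDER_CONCEPTS.get(str(row.sex).strip().upper()[:1], 0),
                "year_of_birth": int(row.birth_year),
                "person_source_value": str(row.patient_id),
            }
        )
    cdm.tables["person"] = (
        pd.DataFrame(person_rows, columns=CDM_COLUMNS["person"])
        .sort_values("person_id")
        .reset_index(drop=True)
    )

    death_rows = []
    for row in source.table("death").itertuples(index=False):
        if row.death_date is None:
            continue
        death_rows.append(
            {
                "person_id": int(row.patient_id),
                "death_date": row.death_date,
                "death_type_concept_id": type_concept,
            }
        )
    cdm.tables["death"] = (
        pd.DataFrame(death_rows, columns=CDM_COLUMNS["death"])
        .sort_values("person_id")
        .reset_index(drop=True)
    )

    # visits straight from the event list
    if entries.empty:
        cdm.tables["visit_occurrence"] = pd.DataFrame(columns=CDM_COLUMNS["visit_occurrence"])
    else:
        visits = (
            entries[["visit_id", "person_id", "event_date"]]
            .drop_duplicates("visit_id")
            .sort_values("visit_id")
        )
        cdm.tables["visit_occurrence"] = pd.DataFrame(
            {
                "visit_occurrence_id": visits["visit_id"].astype(int).values,
                "person_id": visits["person_id"].astype(int).values,
                "visit_concept_id": OUTPATIENT_VISIT_CONCEPT,
                "visit_start_date": visits["event_date"].values,
                "visit_end_date": visits["event_date"].values,
                "visit_type_concept_id": type_concept,
            }
        ).reset_index(drop=True)

    staged: dict[str, list[dict]] = {t: [] for t in _CONCEPT_COLUMN}

    def emit(domain_table, person, concepts, source_value, date, visit, route, row_id, tumor_id):
        for concept_id in concepts if concepts else [0]:
            rec = {
                "person_id": int(person),
                _CONCEPT_COLUMN[domain_table]: int(concept_id),
                _DATE_COLUMN[domain_table]: date,
                _TYPE_COLUMN[domain_table]: type_concept,
                "visit_occurrence_id": visit,
                _SOURCE_COLUMN[domain_table]: source_value,
                "source_item": route.item,
                "source_table": route.source_table,
                "source_row_id": str(row_id),
                "source_tumor_id": str(tumor_id) if tumor_id is not None else "",
            }
            if domain_table == "drug_exposure":
                rec["drug_exposure_end_date"] = date
            staged[domain_table].append(rec)

    row_id_column = {
        "diagnosis": "diagnosis_id",
        "surgery": "surgery_id",
        "substance": "substance_id",
        "radiation": "radiation_id",
        "follow_up": "follow_up_id",
        "side_effect": "side_effect_id",
    }

    therapy_dx = {
        row.therapy_id: row.diagnosis_id
        for row in source.table("systemic_therapy").itertuples(index=False)
    }

    for route in routing:
        frame = source.table(route.source_table)
        if frame.empty or route.column not in frame.columns:
            continue
        id_col = row_id_column[route.source_table]
        for row in frame.itertuples(index=False):
            values = row._asdict()
            code = str(values[route.column]).strip()
            if not code:
                continue
            row_id = values[id_col]
            hit = visit_lookup.get((route.source_table, str(row_id), route.event_kind))
            if hit is None:
                continue  # undated record, excluded from the event list
            visit_id, date = hit
            tumor_id = values.get("diagnosis_id")
            if tumor_id is None and "therapy_id" in values:
                tumor_id = therapy_dx.get(values["therapy_id"])

            if route.domain_table == "drug_exposure" and not route.vocabulary_id:
                mention = normalize_mention(store, code, substance_rules)
                for match in mention.matches:
                    emit(
                        "drug_exposure",
                        values["patient_id"],
                        list(match.concept_ids),
                        code,
                        date,
                        visit_id,
                        route,
                        row_id,
                        tumor_id,
                    )
                continue

            key = (route.vocabulary_id, code)
            concepts = auto.get(key) or manual.get(key) or []
            emit(
                route.domain_table,
                values["patient_id"],
                concepts,
                code,
                date,
                visit_id,
                route,
                row_id,
                tumor_id,
            )

    for domain_table, rows in staged.items():
        columns = CDM_COLUMNS[domain_table] + HELPER_COLUMNS
        frame = pd.DataFrame(rows, columns=columns)
        if not frame.empty:
            frame = frame.sort_values(
                ["person_id", _DATE_COLUMN[domain_table], "source_table", "source_row_id",
                 "source_item", _CONCEPT_COLUMN[domain_table]]
            ).reset_index(drop=True)
        frame[_ID_COLUMN[domain_table]] = range(1, len(frame) + 1)
        cdm.tables[domain_table] = frame[columns]
    return cdm


def write_cdm(cdm: CdmStore, directory: str | Path) -> dict[str, Path]:
    """Dump every CDM table as a CSV with standard v5.4 column names.

    Provenance helper columns are stripped; rows are already in
    deterministic order, so identical inputs produce byte-identical
    files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in sorted(cdm.tables):
        frame = cdm.tables[name]
        cols = [c for c in CDM_COLUMNS.get(name, frame.columns) if c in frame.columns]
        path = directory / f"{name}.csv"
        frame[cols].to_csv(path, index=False)
        written[name] = path
    return written
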