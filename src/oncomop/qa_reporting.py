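"""Logical quality checks and mapping-rate reports for a populated CDM.

Two reporting surfaces:

* an item report — per routed oBDS item, the source row count, the
  count of CDM rows with a resolved (non-zero) concept, and the mapping
  rate ``100 * n_target / n_source``.  One-to-many vocabulary mappings
  legitimately push a rate above 100% (the OPS procedure catalogue is
  the canonical case);
* a fixed core of Achilles-style logical checks over the CDM tables —
  events after death, events before birth, concepts missing from the
  vocabulary store, visits without persons, orphan episode-event links,
  and a configurable unmapped-rate threshold per table.

Integrity violations (checks 1–5) are findings of severity ``error``;
an elevated unmapped rate is a ``warning`` — unmappable source codes
are expected information loss of the harmonization, not a defect of
the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._rounding import percent
from .etl_core import (
    CdmStore,
    _CONCEPT_COLUMN,
    _DATE_COLUMN,
    _ID_COLUMN,
)
from .vocabulary_store import VocabularyStore

__all__ = [
    "QAFinding",
    "ItemReportRow",
    "mapping_rate",
    "build_item_report",
    "run_checks",
    "format_findings",
]


@dataclass(frozen=True)
class QAFinding:
    check_id: str
    severity: str  # "error" | "warning"
    table: str
    count: int
    message: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("a finding requires at least one offending row")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class ItemReportRow:
    item: str
    domain: str
    n_source: int
    n_target: int

    @property
    def rate(self) -> float:
        return mapping_rate(self.n_source, self.n_target)


def mapping_rate(n_source: int, n_target: int) -> float:
    """100 * n_target / n_source, half-up to 2 decimals; may exceed 100."""
    if n_source <= 0:
        raise ValueError("n_source must be positive")
    if n_target < 0:
        raise ValueError("n_target must be non-negative")
    return percent(n_target, n_source)


def build_item_report(cdm: CdmStore) -> pd.DataFrame:
    """Mapping rate per routed oBDS item.

    ``n_source`` counts the CDM rows an item emitted at the source-row
    level (each source row emits at least one target row, so distinct
    (table, row, item) triples recover the source count); ``n_target``
    counts emitted rows with a non-zero concept.
    """
    rows = []
    for table, concept_col in _CONCEPT_COLUMN.items():
        frame = cdm.table(table)
        if frame.empty or "source_item" not in frame.columns:
            continue
        for item, group in frame.groupby("source_item", sort=True):
            n_source = group[["source_table", "source_row_id"]].drop_duplicates().shape[0]
            n_target = int((group[concept_col] != 0).sum())
            rows.append(
                {
                    "item": item,
                    "domain": table,
                    "n_source": n_source,
                    "n_target": n_target,
                    "mapping_rate_pct": mapping_rate(n_source, n_target),
                }
            )
    return pd.DataFrame(
        rows, columns=["item", "domain", "n_source", "n_target", "mapping_rate_pct"]
    ).sort_values(["item", "domain"]).reset_index(drop=True)


def run_checks(
    cdm: CdmStore,
    store: VocabularyStore | None = None,
    episodes: pd.DataFrame | None = None,
    episode_events: pd.DataFrame | None = None,
    unmapped_rate_threshold: float = 0.5,
) -> list[QAFinding]:
    """Run the built-in logical checks; one finding per check+table.

    A clean CDM yields no error findings; every check reports the exact
    number of offending rows.
    """
    findings: list[QAFinding] = []
    person = cdm.table("person")
    death = cdm.table("death")
    death_dates = dict(zip(death["person_id"], death["death_date"]))
    birth_years = dict(zip(person["person_id"], person["year_of_birth"]))
    person_ids = set(person["person_id"])

    clinical = list(_CONCEPT_COLUMN)

    # 1: events dated after the person's death
    for table in clinical:
        frame = cdm.table(table)
        if frame.empty:
            continue
        date_col = _DATE_COLUMN[table]
        n = sum(
            1
            for row in frame.itertuples(index=False)
            if row.person_id in death_dates
            and getattr(row, date_col) > death_dates[row.person_id]
        )
        if n:
            findings.append(
                QAFinding("events_after_death", "error", table, n,
                          f"{n} {table} rows dated after the person's death date")
            )

    # 2: events dated before the person's birth year
    for table in clinical:
        frame = cdm.table(table)
        if frame.empty:
            continue
        date_col = _DATE_COLUMN[table]
        n = sum(
            1
            for row in frame.itertuples(index=False)
            if row.person_id in birth_years
            and getattr(row, date_col).year < birth_years[row.person_id]
        )
        if n:
            findings.append(
                QAFinding("events_before_birth", "error", table, n,
                          f"{n} {table} rows dated before the person's birth year")
            )

    # 3: non-zero concept_ids absent from the vocabulary store
    if store is not None:
        for table in clinical:
            frame = cdm.table(table)
            if frame.empty:
                continue
            concept_col = _CONCEPT_COLUMN[table]
            n = sum(
                1
                for c in frame[concept_col]
                if int(c) != 0 and int(c) not in store
            )
            if n:
                findings.append(
                    QAFinding("concept_not_in_store", "error", table, n,
                              f"{n} {table} rows carry a concept_id missing from the vocabulary")
                )

    # 4: visits referencing no person
    visits = cdm.table("visit_occurrence")
    if not visits.empty:
        n = int((~visits["person_id"].isin(person_ids)).sum())
        if n:
            findings.append(
                QAFinding("visit_without_person", "error", "visit_occurrence", n,
                          f"{n} visits reference a person_id absent from person")
            )

    # 5: episode_event links referencing a missing episode or event row
    if episode_events is not None and not episode_events.empty:
        episode_ids = set() if episodes is None else set(episodes["episode_id"])
        n = 0
        row_ids = {
            table: set(cdm.table(table)[_ID_COLUMN[table]])
            for table in clinical
            if not cdm.table(table).empty
        }
        for row in episode_events.itertuples(index=False):
            if row.episode_id not in episode_ids:
                n += 1
            elif int(row.event_id) not in row_ids.get(row.event_table, set()):
                n += 1
        if n:
            findings.append(
                QAFinding("episode_event_orphan", "error", "episode_event", n,
                          f"{n} episode_event links dangle (missing episode or event row)")
            )

    # 6: unmapped (concept_id = 0) rate per table above threshold
    for table in clinical:
        frame = cdm.table(table)
        if frame.empty:
            continue
        concept_col = _CONCEPT_COLUMN[table]
        n_zero = int((frame[concept_col] == 0).sum())
        rate = n_zero / len(frame)
        if rate > unmapped_rate_threshold:
            findings.append(
                QAFinding("unmapped_rate", "warning", table, n_zero,
                          f"{n_zero}/{len(frame)} rows unmapped "
                          f"({100 * rate:.1f}% > {100 * unmapped_rate_threshold:.1f}%)")
            )
    return findings


def format_findings(findings: Sequence[QAFinding]) -> str:
    if not findings:
        return "QA: no findings\n"
    lines = ["QA findings:"]
    for f in findings:
        lines.append(f"  [{f.severity:7s}] {f.check_id} ({f.table}, n={f.count}): {f.message}")
    return "\n".join(lines) + "\n"


def findings_frame(findings: Sequence[QAFinding]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "check_id": f.check_id,
                "severity": f.severity,
                "table": f.table,
                "count": f.count,
                "message": f.message,
            }
            for f in findings
        ],
        columns=["check_id", "severity", "table", "count", "message"],
    )
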