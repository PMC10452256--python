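"""Classify oBDS expressions into mapping statuses and build look-up tables.

The German oncological basis dataset (oBDS) organizes reporting into
categories (diagnosis, surgery, systemic therapy, ...), items within a
category (ICD-10-GM, OPS, side localization, ...) and expressions — the
individual codes or values an item may take.  Harmonizing a registry to
the OMOP CDM requires a mapping decision per expression:

``automatic``
    the expression's code resolves to a standard concept through the
    vocabulary relationship graph ("Maps to"); these rows feed the
    machine-built *source_to_standard* look-up table.
``manual``
    a curator assigned a target concept (Usagi/Athena style review);
    these rows live in the *source_to_concept* table.
``etl``
    the value is carried over structurally during the ETL (dates,
    direct-column items) and needs no concept at all.
``not_mappable``
    nothing in the standardized vocabularies can represent it (e.g.
    laterality "U"/"B", register-identifying fields).

Precedence is automatic > manual > etl > not_mappable: a
community-maintained vocabulary mapping always wins over a local manual
one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

from ._rounding import percent
from .vocabulary_store import Concept, UnknownCodeError, VocabularyStore, resolve_to_standard

__all__ = [
    "OBDS_CATEGORIES",
    "SourceExpression",
    "MappingRecord",
    "load_manual_table",
    "classify_expression",
    "classify_expressions",
    "build_source_to_standard",
    "suggest_candidates",
    "summarize_statuses",
]

# The 19 in-scope oBDS categories (the 20th, "reporting reason", carries
# consent metadata and is out of scope for a patient-centric CDM).
OBDS_CATEGORIES = (
    "course",
    "death",
    "diagnosis",
    "histology",
    "metastasis",
    "notice",
    "operator",
    "other classification",
    "patient master data",
    "performance",
    "radiation",
    "radiation side effect",
    "register master data",
    "residual status",
    "surgery",
    "systemic therapy",
    "systemic therapy side effect",
    "tnm classification",
    "tumor board",
)

STATUSES = ("automatic", "manual", "etl", "not_mappable")

# Usagi-compatible review-file columns (source_to_concept dialect).
SOURCE_TO_CONCEPT_COLUMNS = [
    "source_code",
    "source_vocabulary_id",
    "source_code_description",
    "target_concept_id",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]


@dataclass(frozen=True)
class SourceExpression:
    """One oBDS item expression (a single code an item may take)."""

    category: str
    item: str
    code: str
    display_en: str = ""
    cardinality: str = "finite"  # finite | free_text | date
    vocabulary_id: str = ""  # vocabulary the code lives in, if any

    def __post_init__(self) -> None:
        if self.category not in OBDS_CATEGORIES:
            raise ValueError(f"unknown oBDS category {self.category!r}")
        if self.cardinality not in ("finite", "free_text", "date"):
            raise ValueError(f"unknown cardinality {self.cardinality!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.category, self.item, self.code)


@dataclass(frozen=True)
class MappingRecord:
    """Resolved mapping status of one source expression."""

    source: tuple[str, str, str]
    status: str
    targets: tuple[int, ...] = ()
    target_domain: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status in ("automatic", "manual") and not self.targets:
            raise ValueError(f"status {self.status!r} requires targets")
        if self.status == "not_mappable" and self.targets:
            raise ValueError("not_mappable records carry no targets")


def load_manual_table(path: str | Path) -> pd.DataFrame:
    """Read a source_to_concept review CSV (Usagi column set)."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SOURCE_TO_CONCEPT_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise ValueError(f"manual mapping table lacks columns: {missing}")
    table["target_concept_id"] = table["target_concept_id"].astype(int)
    return table


def _manual_lookup(manual_table: pd.DataFrame | None, expr: SourceExpression):
    if manual_table is None or manual_table.empty:
        return None
    hits = manual_table[
        (manual_table["source_code"] == expr.code)
        & (
            (manual_table["source_vocabulary_id"] == expr.vocabulary_id)
            | (manual_table["source_vocabulary_id"] == expr.item)
        )
    ]
    if hits.empty:
        return None
    return tuple(int(t) for t in sorted(hits["target_concept_id"].unique()))


def classify_expression(
    expr: SourceExpression,
    store: VocabularyStore,
    manual_table: pd.DataFrame | None = None,
    etl_items: Iterable[str] = (),
) -> MappingRecord:
    """Assign the mapping status of a single expression.

    A manual-table row with ``target_concept_id == 0`` marks an
    expression a curator reviewed and declared unmappable; it is
    classified ``not_mappable`` rather than ``manual``.
    """
    etl_items = set(etl_items)

    # automatic: the expression's own vocabulary code resolves via "Maps to"
    if expr.vocabulary_id:
        try:
            targets = resolve_to_standard(store, (expr.vocabulary_id, expr.code))
        except UnknownCodeError:
            targets = []
        if targets:
            return MappingRecord(
                source=expr.key,
                status="automatic",
                targets=tuple(t.concept_id for t in targets),
                target_domain=targets[0].domain_id,
            )

    manual_targets = _manual_lookup(manual_table, expr)
    if manual_targets is not None:
        real = tuple(t for t in manual_targets if t != 0)
        if real:
            domains = {store.get(t).domain_id for t in real if t in store}
            return MappingRecord(
                source=expr.key,
                status="manual",
                targets=real,
                target_domain=domains.pop() if len(domains) == 1 else "",
            )
        return MappingRecord(source=expr.key, status="not_mappable")

    if expr.cardinality == "date" or expr.item in etl_items:
        return MappingRecord(source=expr.key, status="etl")

    return MappingRecord(source=expr.key, status="not_mappable")


def classify_expressions(
    exprs: Sequence[SourceExpression],
    store: VocabularyStore,
    manual_table: pd.DataFrame | None = None,
    etl_items: Iterable[str] = (),
) -> list[MappingRecord]:
    """Classify a batch of expressions, one record per expression."""
    seen: set[tuple[str, str, str]] = set()
    records = []
    for expr in exprs:
        if expr.key in seen:
            raise ValueError(f"duplicate expression {expr.key}")
        seen.add(expr.key)
        records.append(classify_expression(expr, store, manual_table, etl_items))
    return records


def build_source_to_standard(
    exprs: Sequence[SourceExpression], store: VocabularyStore
) -> pd.DataFrame:
    """Machine-built look-up table for the automatically mappable codes.

    One row per (expression, resolved standard concept); one-to-many
    resolutions expand into multiple rows.  Ordered by (vocabulary,
    code, target concept) so rebuilding is byte-deterministic.
    """
    rows = []
    for expr in exprs:
        if not expr.vocabulary_id:
            continue
        try:
            targets = resolve_to_standard(store, (expr.vocabulary_id, expr.code))
        except UnknownCodeError:
            continue
        for target in targets:
            rows.append(
                {
                    "source_code": expr.code,
                    "source_vocabulary_id": expr.vocabulary_id,
                    "target_concept_id": target.concept_id,
                    "target_domain_id": target.domain_id,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "source_code",
            "source_vocabulary_id",
            "target_concept_id",
            "target_domain_id",
        ],
    )
    return table.sort_values(
        ["source_vocabulary_id", "source_code", "target_concept_id"]
    ).reset_index(drop=True)


def suggest_candidates(
    store: VocabularyStore, query_text: str, k: int = 10
) -> list[tuple[Concept, float]]:
    """Rank concept names against a free-text query (Usagi-style).

    TF-IDF vectors over lowercase word unigrams of every concept name,
    cosine similarity to the query, top-*k* with ties broken by
    ascending ``concept_id``.  Scores lie in [0, 1]; a query identical
    to a concept name scores 1 against it.
    """
    if store.n_concepts == 0:
        raise ValueError("cannot suggest candidates from an empty store")
    concepts = sorted(store.concepts.values(), key=lambda c: c.concept_id)
    names = [c.concept_name for c in concepts]
    vectorizer = TfidfVectorizer(lowercase=True, token_pattern=r"(?u)\b\w+\b")
    matrix = vectorizer.fit_transform(names)
    try:
        query_vec = vectorizer.transform([query_text])
    except ValueError as exc:  # pragma: no cover - vectorizer config dependent
        raise ValueError(f"query {query_text!r} normalizes to nothing: {exc}")
    if query_vec.nnz == 0:
        raise ValueError(f"query {query_text!r} normalizes to nothing")
    scores = cosine_similarity(query_vec, matrix).ravel()
    # stable sort on (-score, concept_id): argsort is stable and the
    # concepts list is already in ascending concept_id order
    order = np.argsort(-scores, kind="stable")[:k]
    return [(concepts[i], float(np.clip(scores[i], 0.0, 1.0))) for i in order]


def summarize_statuses(records: Sequence[MappingRecord]) -> pd.DataFrame:
    """Status counts and percentages per oBDS category and overall.

    Returns one row per (category, status) plus ``overall`` rows and a
    derived ``mappable`` pseudo-status (automatic + manual + etl).
    Percentages are within-category, half-up to two decimals.
    """
    if not records:
        return pd.DataFrame(columns=["category", "status", "count", "pct"])
    per_cat: dict[str, Counter] = {}
    for rec in records:
        per_cat.setdefault(rec.source[0], Counter())[rec.status] += 1

    rows = []
    overall = Counter()
    for category in sorted(per_cat):
        counts = per_cat[category]
        overall.update(counts)
        total = sum(counts.values())
        for status in STATUSES:
            rows.append(
                {
                    "category": category,
                    "status": status,
                    "count": counts.get(status, 0),
                    "pct": percent(counts.get(status, 0), total),
                }
            )
        mappable = total - counts.get("not_mappable", 0)
        rows.append(
            {
                "category": category,
                "status": "mappable",
                "count": mappable,
                "pct": percent(mappable, total),
            }
        )
    total = sum(overall.values())
    for status in STATUSES:
        rows.append(
            {
                "category": "overall",
                "status": status,
                "count": overall.get(status, 0),
                "pct": percent(overall.get(status, 0), total),
            }
        )
    mappable = total - overall.get("not_mappable", 0)
    rows.append(
        {
            "category": "overall",
            "status": "mappable",
            "count": mappable,
            "pct": percent(mappable, total),
        }
    )
    return pd.DataFrame(rows, columns=["category", "status", "count", "pct"])
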