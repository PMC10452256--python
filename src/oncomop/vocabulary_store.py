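"""Load, index and query a standardized-vocabulary export.

The OMOP standardized vocabularies are distributed (via the Athena
service) as tab-delimited ``CONCEPT`` and ``CONCEPT_RELATIONSHIP``
tables.  This module reads such an export into an in-memory
:class:`VocabularyStore`, resolves source codes to *standard* concepts
through valid ``Maps to`` relationship edges, and produces a census of
the relationship graph around a set of concepts.

Conventions implemented here:

* A concept is *standard* when its ``standard_concept`` flag is ``S``,
  a *classification* when ``C``, and *non-standard* otherwise.
* Only ``Maps to`` edges define standard resolution; every other
  relationship (``Subsumes``, ``Mapped from``, ``Asso morph of``, ...)
  is kept for the census but never used to map.
* An edge is valid when its ``valid_end_date`` is on or after the
  store's reference date (by default the latest ``valid_start_date``
  seen in the concept file); Athena exports retain deprecated edges.
* One-to-many resolutions (common for OPS procedure codes) are returned
  in full, ordered by ascending ``concept_id``; collapsing them is the
  caller's responsibility and is deliberately never done here.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._rounding import round_half_up

__all__ = [
    "Concept",
    "RejectedRow",
    "UnknownCodeError",
    "VocabularyStore",
    "load_vocabulary",
    "resolve_to_standard",
    "relationship_census",
    "share_percent",
]

CONCEPT_COLUMNS = [
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "concept_class_id",
    "standard_concept",
    "concept_code",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]

RELATIONSHIP_COLUMNS = [
    "concept_id_1",
    "concept_id_2",
    "relationship_id",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]

MAPS_TO = "Maps to"


class UnknownCodeError(KeyError):
    """A source code or concept_id that is not present in the store."""


@dataclass(frozen=True)
class Concept:
    """One row of the CONCEPT table."""

    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    standard_flag: str  # "standard" | "non_standard" | "classification"
    concept_code: str
    valid_from: dt.date
    valid_to: dt.date

    @property
    def is_standard(self) -> bool:
        return self.standard_flag == "standard"


@dataclass(frozen=True)
class RejectedRow:
    """Per-row load diagnostic for a row that failed an invariant."""

    file: str
    row: int  # 0-based data-row index (header excluded)
    reason: str


def _parse_vocab_date(raw: object) -> dt.date:
    """Athena exports carry dates as YYYYMMDD."""
    s = str(raw).strip()
    return dt.datetime.strptime(s, "%Y%m%d").date()


def _standard_flag(raw: object) -> str:
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip()
    if s == "S":
        return "standard"
    if s == "C":
        return "classification"
    return "non_standard"


@dataclass
class VocabularyStore:
    """Indexed concepts + relationship edges of one vocabulary export."""

    concepts: dict[int, Concept]
    relationships: pd.DataFrame  # validated edge table, ISO dates
    reference_date: dt.date
    rejected: list[RejectedRow] = field(default_factory=list)
    _by_code: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)
    _maps_to: dict[int, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._by_code:
            self._by_code = {
                (c.vocabulary_id, c.concept_code): c.concept_id
                for c in self.concepts.values()
            }
        if not self._maps_to:
            self._maps_to = {}
            for row in self.valid_edges(MAPS_TO).itertuples(index=False):
                self._maps_to.setdefault(int(row.concept_id_1), []).append(
                    int(row.concept_id_2)
                )

    # -- basic access -------------------------------------------------

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_relationships(self) -> int:
        return len(self.relationships)

    def __contains__(self, concept_id: int) -> bool:
        return int(concept_id) in self.concepts

    def get(self, concept_id: int) -> Concept:
        try:
            return self.concepts[int(concept_id)]
        except (KeyError, ValueError, TypeError):
            raise UnknownCodeError(f"unknown concept_id {concept_id!r}") from None

    def lookup_code(self, vocabulary_id: str, concept_code: str) -> Concept:
        """Exact, case-sensitive (vocabulary, code) look-up."""
        cid = self._by_code.get((vocabulary_id, concept_code))
        if cid is None:
            raise UnknownCodeError(
                f"unknown code {concept_code!r} in vocabulary {vocabulary_id!r}"
            )
        return self.concepts[cid]

    def concepts_frame(self) -> pd.DataFrame:
        """Concept index as a DataFrame (one row per concept)."""
        return pd.DataFrame(
            [
                {
                    "concept_id": c.concept_id,
                    "concept_name": c.concept_name,
                    "domain_id": c.domain_id,
                    "vocabulary_id": c.vocabulary_id,
                    "concept_class_id": c.concept_class_id,
                    "standard_flag": c.standard_flag,
                    "concept_code": c.concept_code,
                }
                for c in sorted(self.concepts.values(), key=lambda c: c.concept_id)
            ]
        )

    def valid_edges(self, relationship_id: str | None = None) -> pd.DataFrame:
        """Edges whose valid_to is on/after the store reference date."""
        edges = self.relationships
        if edges.empty:
            return edges
        mask = edges["valid_to"] >= self.reference_date
        if relationship_id is not None:
            mask &= edges["relationship_id"] == relationship_id
        return edges[mask]


def load_vocabulary(directory: str | Path) -> VocabularyStore:
    """Read CONCEPT.csv and CONCEPT_RELATIONSHIP.csv from *directory*.

    Both files are tab-delimited with header rows (the Athena export
    dialect).  Rows violating an invariant (unparseable date,
    ``valid_from > valid_to``, a relationship endpoint that is not a
    loaded concept) are collected in ``store.rejected`` with a per-row
    diagnostic and the load continues.  A missing file or a duplicate
    ``concept_id`` is fatal.
    """
    directory = Path(directory)
    concept_path = directory / "CONCEPT.csv"
    rel_path = directory / "CONCEPT_RELATIONSHIP.csv"
    for p in (concept_path, rel_path):
        if not p.exists():
            raise FileNotFoundError(f"vocabulary file missing: {p}")

    rejected: list[RejectedRow] = []
    concepts: dict[int, Concept] = {}

    raw_c = pd.read_csv(concept_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CONCEPT_COLUMNS[:9] if c not in raw_c.columns]
    if missing:
        raise ValueError(f"CONCEPT.csv lacks required columns: {missing}")

    latest_start: dt.date | None = None
    for i, row in enumerate(raw_c.itertuples(index=False)):
        try:
            cid = int(row.concept_id)
            valid_from = _parse_vocab_date(row.valid_start_date)
            valid_to = _parse_vocab_date(row.valid_end_date)
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedRow("CONCEPT.csv", i, f"malformed field: {exc}"))
            continue
        if valid_from > valid_to:
            rejected.append(
                RejectedRow(
                    "CONCEPT.csv",
                    i,
                    f"valid_start_date {valid_from} after valid_end_date {valid_to}",
                )
            )
            continue
        if cid in concepts:
            raise ValueError(f"duplicate concept_id {cid} in CONCEPT.csv")
        concepts[cid] = Concept(
            concept_id=cid,
            concept_name=str(row.concept_name),
            domain_id=str(row.domain_id),
            vocabulary_id=str(row.vocabulary_id),
            concept_class_id=str(row.concept_class_id),
            standard_flag=_standard_flag(row.standard_concept),
            concept_code=str(row.concept_code),
            valid_from=valid_from,
            valid_to=valid_to,
        )
        if latest_start is None or valid_from > latest_start:
            latest_start = valid_from

    raw_r = pd.read_csv(rel_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RELATIONSHIP_COLUMNS[:5] if c not in raw_r.columns]
    if missing:
        raise ValueError(f"CONCEPT_RELATIONSHIP.csv lacks required columns: {missing}")

    edge_rows = []
    for i, row in enumerate(raw_r.itertuples(index=False)):
        try:
            c1 = int(row.concept_id_1)
            c2 = int(row.concept_id_2)
            valid_from = _parse_vocab_date(row.valid_start_date)
            valid_to = _parse_vocab_date(row.valid_end_date)
        except (ValueError, TypeError) as exc:
            rejected.append(
                RejectedRow("CONCEPT_RELATIONSHIP.csv", i, f"malformed field: {exc}")
            )
            continue
        if valid_from > valid_to:
            rejected.append(
                RejectedRow(
                    "CONCEPT_RELATIONSHIP.csv",
                    i,
                    f"valid_start_date {valid_from} after valid_end_date {valid_to}",
                )
            )
            continue
        if c1 not in concepts or c2 not in concepts:
            rejected.append(
                RejectedRow(
                    "CONCEPT_RELATIONSHIP.csv",
                    i,
                    f"endpoint not in CONCEPT table: ({c1}, {c2})",
                )
            )
            continue
        edge_rows.append(
            {
                "concept_id_1": c1,
                "concept_id_2": c2,
                "relationship_id": str(row.relationship_id),
                "valid_from": valid_from,
                "valid_to": valid_to,
            }
        )

    relationships = pd.DataFrame(
        edge_rows,
        columns=["concept_id_1", "concept_id_2", "relationship_id", "valid_from", "valid_to"],
    )
    reference_date = latest_start if latest_start is not None else dt.date.min
    return VocabularyStore(
        concepts=concepts,
        relationships=relationships,
        reference_date=reference_date,
        rejected=rejected,
    )


def resolve_to_standard(
    store: VocabularyStore,
    source: int | Concept | tuple[str, str],
) -> list[Concept]:
    """Resolve a source concept to its standard concept(s).

    *source* may be a ``concept_id``, a :class:`Concept`, or a
    ``(vocabulary_id, concept_code)`` pair.  Returns every *standard*
    concept reachable over one valid ``Maps to`` edge, ascending by
    ``concept_id``.  A standard concept with no outgoing ``Maps to``
    edge resolves to itself.  An empty list means "not mappable"; an
    unknown source raises :class:`UnknownCodeError` instead — silence
    would be indistinguishable from a genuine mapping gap.
    """
    if isinstance(source, Concept):
        concept = store.get(source.concept_id)
    elif isinstance(source, tuple):
        concept = store.lookup_code(*source)
    else:
        concept = store.get(source)

    targets = {
        t
        for t in store._maps_to.get(concept.concept_id, [])
        if store.concepts[t].is_standard
    }
    if not targets and concept.is_standard:
        targets = {concept.concept_id}
    return [store.concepts[t] for t in sorted(targets)]


def relationship_census(
    store: VocabularyStore,
    concepts: Iterable[int],
    category_of: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Census of valid relationship edges anchored at a concept set.

    Every valid edge whose ``concept_id_1`` lies in *concepts* counts
    once, grouped by ``relationship_id`` and by the category of the
    anchoring concept (``category_of``; missing concepts fall into
    category ``""``).  Returns a tidy frame with columns
    ``relationship_id, category, count, share_pct`` where shares are
    percentages of the grand total rounded to one decimal.
    """
    concept_set = {int(c) for c in concepts}
    unknown = concept_set - set(store.concepts)
    if unknown:
        raise UnknownCodeError(f"census references unknown concept_ids: {sorted(unknown)[:5]}")
    category_of = category_of or {}

    columns = ["relationship_id", "category", "count", "share_pct"]
    if not concept_set:
        return pd.DataFrame(columns=columns)
    edges = store.valid_edges()
    edges = edges[edges["concept_id_1"].isin(concept_set)]
    if edges.empty:
        return pd.DataFrame(columns=columns)

    cat = edges["concept_id_1"].map(lambda c: category_of.get(int(c), ""))
    grouped = (
        edges.assign(category=cat)
        .groupby(["relationship_id", "category"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    total = int(grouped["count"].sum())
    grouped["share_pct"] = [share_percent(int(n), total) for n in grouped["count"]]
    return grouped.sort_values(
        ["count", "relationship_id", "category"], ascending=[False, True, True]
    ).reset_index(drop=True)[columns]


def share_percent(count: int, total: int) -> float:
    """Share of a census cell as percent, one decimal, half-up."""
    if total == 0:
        raise ValueError("share of an empty census is undefined")
    return round_half_up(100.0 * count / total, 1)


def census_totals(census: pd.DataFrame) -> pd.Series:
    """Marginal counts per relationship_id of a census frame."""
    if census.empty:
        return pd.Series(dtype=int)
    return census.groupby("relationship_id")["count"].sum().sort_values(ascending=False)
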