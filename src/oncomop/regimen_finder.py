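"""Derive treatment regimens from drug exposures by 30-day windowing.

Chemotherapy is reported drug-by-drug, but research questions ask about
*regimens* — named ingredient combinations (HemOnc-style).  The
derivation aggregates, per patient, every drug ingredient administered
within a trailing window (default 30 days) anchored at each exposure
date, and matches the window's ingredient set against a reference table
of regimen → ingredient sets:

* a regimen matches a window when its full ingredient set is contained
  in the window's set (subset matching, so concomitant supportive drugs
  do not break the match);
* among matching regimens the one with the most ingredients wins, ties
  broken by ascending regimen concept_id;
* consecutive anchors yielding the same regimen with overlapping
  windows merge into a single assignment spanning their union.

The matcher is deterministic and translation-invariant: shifting all of
a patient's dates by a constant shifts the assignments identically.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._rounding import percent

__all__ = [
    "DrugExposureEvent",
    "RegimenAssignment",
    "load_regimen_reference",
    "find_regimens",
    "regimen_mapping_rate",
]


@dataclass(frozen=True)
class DrugExposureEvent:
    """One dated ingredient administration for one person."""

    person_id: int
    ingredient_concept_id: int
    start_date: dt.date
    visit_id: int | None = None


@dataclass(frozen=True)
class RegimenAssignment:
    """One derived regimen era for one person."""

    person_id: int
    regimen_concept_id: int
    window_start: dt.date
    window_end: dt.date
    exposures: tuple[DrugExposureEvent, ...] = ()


def load_regimen_reference(path: str | Path) -> dict[int, frozenset[int]]:
    """Read a regimen_ingredients CSV into {regimen_id: ingredient set}.

    Expected columns: ``regimen_concept_id, ingredient_concept_id``.
    """
    table = pd.read_csv(path)
    missing = [
        c
        for c in ("regimen_concept_id", "ingredient_concept_id")
        if c not in table.columns
    ]
    if missing:
        raise ValueError(f"regimen reference lacks columns: {missing}")
    reference: dict[int, set[int]] = {}
    for row in table.itertuples(index=False):
        reference.setdefault(int(row.regimen_concept_id), set()).add(
            int(row.ingredient_concept_id)
        )
    return {rid: frozenset(ings) for rid, ings in reference.items()}


def _best_match(
    window_set: set[int], reference: dict[int, frozenset[int]]
) -> int | None:
    best: tuple[int, int] | None = None  # (-size, regimen_id)
    for regimen_id, ingredients in reference.items():
        if ingredients <= window_set:
            key = (-len(ingredients), regimen_id)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def find_regimens(
    exposures: Iterable[DrugExposureEvent],
    reference: dict[int, frozenset[int]],
    window_days: int = 30,
) -> list[RegimenAssignment]:
    """Match windowed ingredient sets against the regimen reference.

    Each exposure date anchors a window reaching ``window_days``
    backwards (inclusive on both ends).  Returns merged assignments
    ordered by (person, window_start, regimen).
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    by_person: dict[int, list[DrugExposureEvent]] = {}
    for e in exposures:
        by_person.setdefault(e.person_id, []).append(e)

    assignments: list[RegimenAssignment] = []
    for person_id in sorted(by_person):
        events = sorted(
            by_person[person_id],
            key=lambda e: (e.start_date, e.ingredient_concept_id),
        )
        raw: list[RegimenAssignment] = []
        for anchor in events:
            start = anchor.start_date - dt.timedelta(days=window_days)
            end = anchor.start_date
            in_window = tuple(
                e for e in events if start <= e.start_date <= end
            )
            window_set = {e.ingredient_concept_id for e in in_window}
            regimen_id = _best_match(window_set, reference)
            if regimen_id is None:
                continue
            contributing = tuple(
                e
                for e in in_window
                if e.ingredient_concept_id in reference[regimen_id]
            )
            raw.append(
                RegimenAssignment(
                    person_id=person_id,
                    regimen_concept_id=regimen_id,
                    window_start=start,
                    window_end=end,
                    exposures=contributing,
                )
            )
        assignments.extend(_merge_overlapping(raw))
    return assignments


def _merge_overlapping(
    raw: Sequence[RegimenAssignment],
) -> list[RegimenAssignment]:
    """Merge same-regimen assignments whose windows overlap or touch."""
    merged: dict[int, list[RegimenAssignment]] = {}
    for a in sorted(raw, key=lambda a: (a.regimen_concept_id, a.window_start)):
        bucket = merged.setdefault(a.regimen_concept_id, [])
        if bucket and a.window_start <= bucket[-1].window_end:
            prev = bucket[-1]
            exposures = prev.exposures + tuple(
                e for e in a.exposures if e not in prev.exposures
            )
            bucket[-1] = RegimenAssignment(
                person_id=prev.person_id,
                regimen_concept_id=prev.regimen_concept_id,
                window_start=prev.window_start,
                window_end=max(prev.window_end, a.window_end),
                exposures=exposures,
            )
        else:
            bucket.append(a)
    out = [a for bucket in merged.values() for a in bucket]
    return sorted(out, key=lambda a: (a.window_start, a.regimen_concept_id))


def regimen_mapping_rate(n_candidates: int, n_derived: int) -> float:
    """Share of free-text therapy entries yielding a derived regimen.

    ``100 * n_derived / n_candidates`` rounded half-up to two decimals.
    """
    if n_candidates <= 0:
        raise ValueError("n_candidates must be positive")
    if n_derived < 0:
        raise ValueError("n_derived must be non-negative")
    return percent(n_derived, n_candidates)
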