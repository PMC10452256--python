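"""Derive cancer episodes from CDM rows (OMOP oncology extension).

The oncology extension of the OMOP CDM abstracts individual clinical
events into *episodes*:

``treatment``
    one episode per (person, modality, therapy block), where a block
    groups same-modality events whose gaps do not exceed ``gap_days``
    (default 30); surgical interventions are single-day episodes.
``disease_dynamic``
    one episode per follow-up assessment, carrying the remission state
    (complete/partial remission, stable disease, progression) as its
    object concept — concept 0 when the registry code was unmappable.
``disease_extent``
    one episode per (person, tumor, staging date), linking the T/N/M
    rows that support it.
``regimen``
    one episode per derived regimen assignment, one-to-one with the
    regimen finder's output.

Every episode links at least one constituent CDM row through the
``episode_event`` table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .etl_core import CdmStore, REGISTRY_TYPE_CONCEPT
from .regimen_finder import RegimenAssignment

__all__ = [
    "Episode",
    "EpisodeSet",
    "EPISODE_CLASS_CONCEPTS",
    "MODALITY_CONCEPTS",
    "build_treatment_episodes",
    "build_disease_dynamic_episodes",
    "build_disease_extent_episodes",
    "build_regimen_episodes",
    "build_overall_disease_episodes",
    "build_all_episodes",
    "episodes_frame",
    "episode_events_frame",
]

# Episode concept per concept class (oncology-extension convention).
EPISODE_CLASS_CONCEPTS = {
    "treatment": 32531,
    "disease_dynamic": 32677,
    "disease_extent": 32528,
    "regimen": 32531,
    "overall_disease": 32528,
}

# Object concepts for treatment modalities (SNOMED procedure groupers).
MODALITY_CONCEPTS = {
    "surgery": 4301351,
    "drug_therapy": 4273629,
    "radiation": 4029715,
}


@dataclass
class Episode:
    episode_id: int
    person_id: int
    episode_class: str
    object_concept_id: int
    start_date: dt.date
    end_date: dt.date
    parent_episode_id: int | None = None
    events: list[tuple[str, int]] = field(default_factory=list)  # (table, row id)

    def __post_init__(self) -> None:
        if self.episode_class not in EPISODE_CLASS_CONCEPTS:
            raise ValueError(f"unknown episode class {self.episode_class!r}")
        if self.end_date < self.start_date:
            raise ValueError("episode end before start")


@dataclass
class EpisodeSet:
    """Episodes plus their event links, with a shared id sequence."""

    episodes: list[Episode] = field(default_factory=list)
    _next_id: int = 1

    def add(
        self,
        person_id: int,
        episode_class: str,
        object_concept_id: int,
        start_date: dt.date,
        end_date: dt.date,
        events: Sequence[tuple[str, int]],
        parent_episode_id: int | None = None,
    ) -> Episode:
        if not events:
            raise ValueError("an episode must link at least one event")
        ep = Episode(
            episode_id=self._next_id,
            person_id=int(person_id),
            episode_class=episode_class,
            object_concept_id=int(object_concept_id),
            start_date=start_date,
            end_date=end_date,
            parent_episode_id=parent_episode_id,
            events=list(events),
        )
        self.episodes.append(ep)
        self._next_id += 1
        return ep

    def of_class(self, episode_class: str) -> list[Episode]:
        return [e for e in self.episodes if e.episode_class == episode_class]


def _blocks(dates: list[dt.date], gap_days: int) -> list[list[int]]:
    """Indices of *sorted* dates grouped with gaps <= gap_days."""
    blocks: list[list[int]] = []
    for i, d in enumerate(dates):
        if blocks and (d - dates[blocks[-1][-1]]).days <= gap_days:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


def build_treatment_episodes(
    cdm: CdmStore, episodes: EpisodeSet | None = None, gap_days: int = 30
) -> EpisodeSet:
    """Group therapy rows into modality blocks.

    Surgeries produce one single-day episode per (person, date); drug
    and radiation rows are chained per person with the gap rule.
    """
    episodes = episodes or EpisodeSet()

    procedures = cdm.table("procedure_occurrence")
    surgeries = procedures[procedures["source_table"] == "surgery"]
    for (person, date), group in surgeries.groupby(["person_id", "procedure_date"], sort=True):
        episodes.add(
            person_id=person,
            episode_class="treatment",
            object_concept_id=MODALITY_CONCEPTS["surgery"],
            start_date=date,
            end_date=date,
            events=[("procedure_occurrence", int(i)) for i in group["procedure_occurrence_id"]],
        )

    modality_rows = [
        ("drug_therapy", cdm.table("drug_exposure"), "drug_exposure",
         "drug_exposure_start_date", "drug_exposure_id"),
        ("radiation", procedures[procedures["source_table"] == "radiation"],
         "procedure_occurrence", "procedure_date", "procedure_occurrence_id"),
    ]
    for modality, frame, table_name, date_col, id_col in modality_rows:
        if frame.empty:
            continue
        for person, group in frame.groupby("person_id", sort=True):
            group = group.sort_values([date_col, id_col])
            dates = list(group[date_col])
            ids = list(group[id_col])
            for block in _blocks(dates, gap_days):
                episodes.add(
                    person_id=person,
                    episode_class="treatment",
                    object_concept_id=MODALITY_CONCEPTS[modality],
                    start_date=dates[block[0]],
                    end_date=dates[block[-1]],
                    events=[(table_name, int(ids[i])) for i in block],
                )
    return episodes


def build_disease_dynamic_episodes(
    cdm: CdmStore, episodes: EpisodeSet | None = None
) -> EpisodeSet:
    """One remission-status episode per follow-up assessment row."""
    episodes = episodes or EpisodeSet()
    observations = cdm.table("observation")
    followups = observations[observations["source_item"] == "Remission status"]
    for row in followups.sort_values("observation_id").itertuples(index=False):
        episodes.add(
            person_id=row.person_id,
            episode_class="disease_dynamic",
            object_concept_id=int(row.observation_concept_id),
            start_date=row.observation_date,
            end_date=row.observation_date,
            events=[("observation", int(row.observation_id))],
        )
    return episodes


def build_disease_extent_episodes(
    cdm: CdmStore, episodes: EpisodeSet | None = None
) -> EpisodeSet:
    """One disease-extent episode per (person, tumor, staging date)."""
    episodes = episodes or EpisodeSet()
    observations = cdm.table("observation")
    tnm = observations[observations["source_item"].isin(("TNM-T", "TNM-N", "TNM-M"))]
    if tnm.empty:
        return episodes
    for (person, tumor, date), group in tnm.groupby(
        ["person_id", "source_tumor_id", "observation_date"], sort=True
    ):
        episodes.add(
            person_id=person,
            episode_class="disease_extent",
            object_concept_id=EPISODE_CLASS_CONCEPTS["disease_extent"],
            start_date=date,
            end_date=date,
            events=[("observation", int(i)) for i in sorted(group["observation_id"])],
        )
    return episodes


def build_regimen_episodes(
    assignments: Sequence[RegimenAssignment],
    cdm: CdmStore,
    episodes: EpisodeSet | None = None,
) -> EpisodeSet:
    """One episode per regimen assignment (one-to-one).

    Each assignment's contributing exposures are re-identified in the
    drug_exposure table by (person, ingredient, date); the episode span
    is the span of the contributing exposures.
    """
    episodes = episodes or EpisodeSet()
    drugs = cdm.table("drug_exposure")
    index: dict[tuple[int, int, dt.date], list[int]] = {}
    for row in drugs.itertuples(index=False):
        index.setdefault(
            (int(row.person_id), int(row.drug_concept_id), row.drug_exposure_start_date),
            [],
        ).append(int(row.drug_exposure_id))
    for a in assignments:
        linked: list[tuple[str, int]] = []
        for e in a.exposures:
            for rid in index.get(
                (e.person_id, e.ingredient_concept_id, e.start_date), []
            ):
                if ("drug_exposure", rid) not in linked:
                    linked.append(("drug_exposure", rid))
        if not linked:
            continue  # assignment not backed by CDM rows (foreign input)
        exposure_dates = [e.start_date for e in a.exposures]
        episodes.add(
            person_id=a.person_id,
            episode_class="regimen",
            object_concept_id=a.regimen_concept_id,
            start_date=min(exposure_dates),
            end_date=max(exposure_dates),
            events=linked,
        )
    return episodes


def build_overall_disease_episodes(
    cdm: CdmStore, episodes: EpisodeSet
) -> EpisodeSet:
    """Optional parent episodes spanning first diagnosis to last event."""
    conditions = cdm.table("condition_occurrence")
    dx = conditions[conditions["source_item"] == "ICD-10-GM"]
    if dx.empty:
        return episodes
    last_event: dict[int, dt.date] = {}
    for table, date_col, id_col in (
        ("condition_occurrence", "condition_start_date", "condition_occurrence_id"),
        ("procedure_occurrence", "procedure_date", "procedure_occurrence_id"),
        ("drug_exposure", "drug_exposure_start_date", "drug_exposure_id"),
        ("observation", "observation_date", "observation_id"),
        ("measurement", "measurement_date", "measurement_id"),
    ):
        frame = cdm.table(table)
        for row in frame.itertuples(index=False):
            d = getattr(row, date_col)
            pid = int(row.person_id)
            if pid not in last_event or d > last_event[pid]:
                last_event[pid] = d
    for person, group in dx.groupby("person_id", sort=True):
        first = min(group["condition_start_date"])
        parent = episodes.add(
            person_id=person,
            episode_class="overall_disease",
            object_concept_id=EPISODE_CLASS_CONCEPTS["overall_disease"],
            start_date=first,
            end_date=max(last_event.get(int(person), first), first),
            events=[("condition_occurrence", int(group["condition_occurrence_id"].iloc[0]))],
        )
        for ep in episodes.episodes:
            if (
                ep.person_id == parent.person_id
                and ep.parent_episode_id is None
                and ep.episode_id != parent.episode_id
            ):
                ep.parent_episode_id = parent.episode_id
    return episodes


def build_all_episodes(
    cdm: CdmStore,
    assignments: Sequence[RegimenAssignment] = (),
    gap_days: int = 30,
    overall_disease: bool = False,
) -> EpisodeSet:
    episodes = EpisodeSet()
    build_treatment_episodes(cdm, episodes, gap_days=gap_days)
    build_disease_dynamic_episodes(cdm, episodes)
    build_disease_extent_episodes(cdm, episodes)
    build_regimen_episodes(assignments, cdm, episodes)
    if overall_disease:
        build_overall_disease_episodes(cdm, episodes)
    return episodes


def episodes_frame(episodes: EpisodeSet) -> pd.DataFrame:
    """Episode table with oncology-extension column names."""
    rows = [
        {
            "episode_id": e.episode_id,
            "person_id": e.person_id,
            "episode_concept_id": EPISODE_CLASS_CONCEPTS[e.episode_class],
            "episode_start_date": e.start_date,
            "episode_end_date": e.end_date,
            "episode_object_concept_id": e.object_concept_id,
            "episode_type_concept_id": REGISTRY_TYPE_CONCEPT,
            "episode_parent_id": e.parent_episode_id,
            "episode_class": e.episode_class,
        }
        for e in episodes.episodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "episode_id",
            "person_id",
            "episode_concept_id",
            "episode_start_date",
            "episode_end_date",
            "episode_object_concept_id",
            "episode_type_concept_id",
            "episode_parent_id",
            "episode_class",
        ],
    )


def episode_events_frame(episodes: EpisodeSet) -> pd.DataFrame:
    """episode_event link table: (episode, event table, event row)."""
    rows = [
        {"episode_id": e.episode_id, "event_table": table, "event_id": event_id}
        for e in episodes.episodes
        for table, event_id in e.events
    ]
    return pd.DataFrame(rows, columns=["episode_id", "event_table", "event_id"])
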