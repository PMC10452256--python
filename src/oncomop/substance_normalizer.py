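"""Clean free-text substance strings and map them to drug concepts.

Registries receive systemic-therapy substances as free text: trade
names, dosages, schedules and several substances joined in one field
("Cisplatin 75mg/m2 + Etoposid").  Cleaning is an ordered list of
(regex, replacement) rules — shipped as a plain YAML file so a registry
can override it — followed by fixed splitting on the separators
``+ / , und``, lowercasing and whitespace collapsing.  Cleaned names
are then matched exactly (case-insensitive) against Drug-domain
concept names and resolved to standard drug concepts; there is no
fuzzy fallback, so an unmatched name stays an explicit unmapped marker
carrying its source value.  Mapping free text this way loses data by
design: the mapped count is never larger than the mention count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .vocabulary_store import Concept, VocabularyStore, resolve_to_standard

__all__ = [
    "SubstanceMention",
    "SubstanceMatch",
    "load_rules",
    "save_rules",
    "default_rules",
    "clean_substance_text",
    "map_substance",
    "normalize_mention",
]

# separators between substances within one free-text field; the dosage
# rules must run first so "75mg/m2" does not split on its "/"
_SPLIT = re.compile(r"[+/,;]|\bund\b", re.IGNORECASE)
_WS = re.compile(r"\s+")


def default_rules() -> list[tuple[str, str]]:
    """The shipped cleaning rule set (ordered patterns)."""
    text = resources.files("oncomop.data").joinpath("substance_rules.yaml").read_text()
    return _parse_rules(yaml.safe_load(text))


def load_rules(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        return _parse_rules(yaml.safe_load(fh))


def save_rules(rules: list[tuple[str, str]], path: str | Path) -> None:
    payload = {"rules": [{"pattern": p, "replacement": r} for p, r in rules]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def _parse_rules(doc: object) -> list[tuple[str, str]]:
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ValueError("rule file must contain a top-level 'rules' list")
    rules = []
    for entry in doc["rules"]:
        rules.append((str(entry["pattern"]), str(entry.get("replacement", ""))))
    return rules


def clean_substance_text(
    raw: str, rules: list[tuple[str, str]] | None = None
) -> list[str]:
    """Normalize one raw substance field into a list of clean names.

    Deterministic and order-preserving; duplicates are dropped; an
    empty result is legitimate (pure-noise input).  Idempotent on its
    own output: cleaning a cleaned name changes nothing.
    """
    if rules is None:
        rules = default_rules()
    text = raw
    for pattern, replacement in rules:
        text = re.sub(pattern, replacement, text)
    names: list[str] = []
    for part in _SPLIT.split(text):
        name = _WS.sub(" ", part).strip().lower()
        if name and name not in names:
            names.append(name)
    return names


@dataclass(frozen=True)
class SubstanceMatch:
    """Outcome of mapping one cleaned substance name."""

    name: str
    concept_ids: tuple[int, ...] = ()

    @property
    def mapped(self) -> bool:
        return bool(self.concept_ids)


@dataclass
class SubstanceMention:
    """A raw substance field with its cleaned names and drug concepts."""

    raw: str
    cleaned: list[str] = field(default_factory=list)
    matches: list[SubstanceMatch] = field(default_factory=list)

    @property
    def matched_concepts(self) -> list[int]:
        out: list[int] = []
        for m in self.matches:
            out.extend(c for c in m.concept_ids if c not in out)
        return out


def map_substance(store: VocabularyStore, name: str) -> SubstanceMatch:
    """Map a cleaned name to standard drug concepts by exact name match.

    The name is compared case-insensitively against the concept_name of
    every Drug-domain concept (RxNorm ingredients, ATC classes, ...);
    each hit is pushed through ``Maps to`` resolution so a non-standard
    ATC name still lands on its standard RxNorm ingredient.  No hit →
    unmapped marker preserving the source value.
    """
    needle = name.strip().lower()
    target_ids: set[int] = set()
    for concept in store.concepts.values():
        if concept.domain_id == "Drug" and concept.concept_name.lower() == needle:
            for std in resolve_to_standard(store, concept.concept_id):
                if std.domain_id == "Drug":
                    target_ids.add(std.concept_id)
    return SubstanceMatch(name=name, concept_ids=tuple(sorted(target_ids)))


def normalize_mention(
    store: VocabularyStore, raw: str, rules: list[tuple[str, str]] | None = None
) -> SubstanceMention:
    """Clean one raw field and map every resulting name."""
    cleaned = clean_substance_text(raw, rules)
    return SubstanceMention(
        raw=raw,
        cleaned=cleaned,
        matches=[map_substance(store, name) for name in cleaned],
    )
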