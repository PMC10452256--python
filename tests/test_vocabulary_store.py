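"""Vocabulary loading, standard-concept resolution and relationship census."""

import datetime as dt

import numpy as np
import pytest

from oncomop.vocabulary_store import (
    UnknownCodeError,
    load_vocabulary,
    relationship_census,
    resolve_to_standard,
    share_percent,
)

from conftest import write_vocab


def _basic_concepts():
    return [
        (1, "Standard condition", "Condition", "SNOMED", "Finding", "S", "111"),
        (2, "Source code A", "Condition", "ICD10GM", "Code", "", "A01"),
        (3, "Standard target one", "Procedure", "SNOMED", "Procedure", "S", "222"),
        (4, "Standard target two", "Procedure", "SNOMED", "Procedure", "S", "333"),
        (5, "Source OPS code", "Procedure", "OPS", "Code", "", "5-001"),
    ]


class TestLoading:
    def test_counts_and_empty_edge_index(self, tmp_path):
        d = write_vocab(tmp_path / "v", _basic_concepts(), [])
        store = load_vocabulary(d)
        assert store.n_concepts == 5
        assert store.n_relationships == 0
        assert store.valid_edges().empty

    def test_row_violating_date_invariant_is_rejected(self, tmp_path):
        concepts = _basic_concepts()
        concepts.append((9, "Bad dates", "Condition", "SNOMED", "Finding", "S", "999",
                         "20200101", "20100101"))
        d = write_vocab(tmp_path / "v", concepts, [])
        store = load_vocabulary(d)
        assert store.n_concepts == 5  # N-1 of the 6 rows
        assert len(store.rejected) == 1
        assert "valid_start_date" in store.rejected[0].reason

    def test_relationship_with_missing_endpoint_is_rejected(self, tmp_path):
        d = write_vocab(tmp_path / "v", _basic_concepts(), [(2, 77777, "Maps to")])
        store = load_vocabulary(d)
        assert store.n_relationships == 0
        assert any("endpoint" in r.reason for r in store.rejected)

    def test_duplicate_concept_id_is_fatal(self, tmp_path):
        concepts = _basic_concepts() + [_basic_concepts()[0]]
        d = write_vocab(tmp_path / "v", concepts, [])
        with pytest.raises(ValueError, match="duplicate concept_id"):
            load_vocabulary(d)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_vocabulary(tmp_path / "nowhere")


class TestResolution:
    @pytest.mark.parametrize(
        "code,expected",
        [("R", 36770058), ("L", 36770232), ("M", 36770562)],
    )
    def test_laterality_resolves_to_cancer_modifier_concept(
        self, vocab_fixture, code, expected
    ):
        hits = resolve_to_standard(vocab_fixture.store, ("Cancer Modifier", code))
        assert [c.concept_id for c in hits] == [expected]

    def test_standard_concept_without_edges_resolves_to_itself(self, tmp_path):
        store = load_vocabulary(write_vocab(tmp_path / "v", _basic_concepts(), []))
        assert [c.concept_id for c in resolve_to_standard(store, 1)] == [1]

    def test_one_to_many_returns_all_targets_ascending(self, tmp_path):
        store = load_vocabulary(
            write_vocab(tmp_path / "v", _basic_concepts(),
                        [(5, 4, "Maps to"), (5, 3, "Maps to")])
        )
        assert [c.concept_id for c in resolve_to_standard(store, ("OPS", "5-001"))] == [3, 4]

    def test_unknown_code_raises_not_empty(self, tmp_path):
        store = load_vocabulary(write_vocab(tmp_path / "v", _basic_concepts(), []))
        with pytest.raises(UnknownCodeError):
            resolve_to_standard(store, ("ICD10GM", "Z99.9"))
        with pytest.raises(UnknownCodeError):
            resolve_to_standard(store, 123456)

    def test_deprecated_edge_is_ignored(self, tmp_path):
        # the late-starting concept pins the store reference date to 2020,
        # after which the first edge has expired
        concepts = _basic_concepts() + [
            (6, "Release anchor", "Metadata", "SNOMED", "Metadata", "S", "anchor",
             "20200101", "20991231"),
        ]
        store = load_vocabulary(
            write_vocab(
                tmp_path / "v",
                concepts,
                [(2, 1, "Maps to", "20100101", "20110101"),  # expired
                 (5, 3, "Maps to")],
            )
        )
        assert resolve_to_standard(store, ("ICD10GM", "A01")) == []

    def test_resolution_is_idempotent_on_fixture(self, vocab_fixture):
        store = vocab_fixture.store
        for concept in store.concepts.values():
            for std in resolve_to_standard(store, concept.concept_id):
                again = resolve_to_standard(store, std.concept_id)
                assert [c.concept_id for c in again] == [std.concept_id]

    def test_resolution_matches_brute_force_edge_scan(self, vocab_fixture):
        """Oracle: scan every valid Maps-to edge directly."""
        store = vocab_fixture.store
        edges = store.valid_edges("Maps to")
        for concept in store.concepts.values():
            expected = sorted(
                {
                    int(r.concept_id_2)
                    for r in edges.itertuples(index=False)
                    if int(r.concept_id_1) == concept.concept_id
                    and store.concepts[int(r.concept_id_2)].is_standard
                }
            )
            if not expected and concept.is_standard:
                expected = [concept.concept_id]
            got = [c.concept_id for c in resolve_to_standard(store, concept.concept_id)]
            assert got == expected, concept


class TestCensus:
    def test_empty_concept_set_yields_empty_census(self, vocab_fixture):
        census = relationship_census(vocab_fixture.store, set())
        assert census.empty

    def test_share_formula_one_decimal(self):
        assert share_percent(198_089, 380_343) == 52.1
        assert share_percent(59_342, 380_343) == 15.6
        with pytest.raises(ValueError):
            share_percent(1, 0)

    def test_census_equals_exhaustive_enumeration(self, vocab_fixture):
        store = vocab_fixture.store
        rng = np.random.default_rng(3)
        ids = sorted(store.concepts)
        subset = {int(c) for c in rng.choice(ids, size=10, replace=False)}
        category_of = {c: ("even" if c % 2 == 0 else "odd") for c in subset}
        census = relationship_census(store, subset, category_of)

        counts = {}
        for r in store.relationships.itertuples(index=False):
            if r.valid_to < store.reference_date:
                continue
            if int(r.concept_id_1) in subset:
                key = (r.relationship_id, category_of[int(r.concept_id_1)])
                counts[key] = counts.get(key, 0) + 1
        got = {
            (r.relationship_id, r.category): int(r.count)
            for r in census.itertuples(index=False)
        }
        assert got == counts
        assert int(census["count"].sum()) == sum(counts.values())

    def test_shares_sum_to_one_hundred(self, vocab_fixture):
        store = vocab_fixture.store
        census = relationship_census(store, set(store.concepts))
        assert abs(census["share_pct"].sum() - 100.0) <= 0.1 * max(1, len(census))

    def test_unknown_concept_in_set_raises(self, vocab_fixture):
        with pytest.raises(UnknownCodeError):
            relationship_census(vocab_fixture.store, {987654321})
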