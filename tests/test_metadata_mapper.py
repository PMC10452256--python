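"""Expression classification, look-up tables, TF-IDF suggestion, summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_extraction.text import TfidfVectorizer

from oncomop.metadata_mapper import (
    MappingRecord,
    SourceExpression,
    build_source_to_standard,
    classify_expression,
    classify_expressions,
    suggest_candidates,
    summarize_statuses,
)
from oncomop.synthetic_data import build_expressions


def _expr(code, item="Laterality", category="diagnosis", vocab="Cancer Modifier",
          cardinality="finite"):
    return SourceExpression(category, item, code, code, cardinality, vocab)


def _manual_table(rows):
    return pd.DataFrame(
        rows,
        columns=["source_code", "source_vocabulary_id", "source_code_description",
                 "target_concept_id", "valid_start_date", "valid_end_date",
                 "invalid_reason"],
    )


class TestClassification:
    def test_mappable_laterality_is_automatic(self, vocab_fixture):
        rec = classify_expression(_expr("R"), vocab_fixture.store)
        assert rec.status == "automatic"
        assert rec.targets == (36770058,)

    def test_unmappable_laterality_falls_through(self, vocab_fixture):
        rec = classify_expression(_expr("U"), vocab_fixture.store)
        assert rec.status == "not_mappable"
        assert rec.targets == ()

    def test_date_items_map_during_etl(self, vocab_fixture):
        rec = classify_expression(
            _expr("<date>", item="Diagnosis date", category="course",
                  vocab="", cardinality="date"),
            vocab_fixture.store,
        )
        assert rec.status == "etl"

    def test_etl_item_names_apply_to_non_date_items(self, vocab_fixture):
        rec = classify_expression(
            _expr("42", item="Direct column", category="course", vocab=""),
            vocab_fixture.store,
            etl_items={"Direct column"},
        )
        assert rec.status == "etl"

    def test_manual_table_supplies_targets(self, vocab_fixture):
        manual = _manual_table(
            [("PERK", "OBDS-RADIATION", "percutaneous", 4460001, "", "", "")]
        )
        rec = classify_expression(
            _expr("PERK", item="Radiation type", category="radiation",
                  vocab="OBDS-RADIATION"),
            vocab_fixture.store,
            manual_table=manual,
        )
        assert rec.status == "manual"
        assert rec.targets == (4460001,)

    def test_manual_zero_target_means_reviewed_unmappable(self, vocab_fixture):
        manual = _manual_table([("X", "OBDS-RADIATION", "other", 0, "", "", "")])
        rec = classify_expression(
            _expr("X", item="Radiation type", category="radiation",
                  vocab="OBDS-RADIATION"),
            vocab_fixture.store,
            manual_table=manual,
        )
        assert rec.status == "not_mappable"

    def test_automatic_wins_over_manual(self, vocab_fixture):
        manual = _manual_table([("R", "Cancer Modifier", "right", 4460001, "", "", "")])
        rec = classify_expression(_expr("R"), vocab_fixture.store, manual_table=manual)
        assert rec.status == "automatic"
        assert rec.targets == (36770058,)

    def test_partition_every_expression_exactly_one_status(self, vocab_fixture):
        exprs = build_expressions(vocab_fixture.store)
        records = classify_expressions(exprs, vocab_fixture.store)
        assert len(records) == len(exprs)
        assert {r.source for r in records} == {e.key for e in exprs}

    def test_valid_maps_to_chain_is_never_not_mappable(self, vocab_fixture):
        store = vocab_fixture.store
        exprs = build_expressions(store)
        for expr, rec in zip(exprs, classify_expressions(exprs, store)):
            if not expr.vocabulary_id:
                continue
            try:
                concept = store.lookup_code(expr.vocabulary_id, expr.code)
            except Exception:
                continue
            has_chain = bool(
                [c for c in store._maps_to.get(concept.concept_id, [])
                 if store.concepts[c].is_standard]
            ) or concept.is_standard
            if has_chain:
                assert rec.status != "not_mappable", expr

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            MappingRecord(("diagnosis", "x", "y"), "automatic", ())
        with pytest.raises(ValueError):
            MappingRecord(("diagnosis", "x", "y"), "not_mappable", (1,))


class TestSourceToStandard:
    def test_empty_input_empty_table(self, vocab_fixture):
        assert build_source_to_standard([], vocab_fixture.store).empty

    def test_laterality_yields_one_row(self, vocab_fixture):
        table = build_source_to_standard([_expr("R")], vocab_fixture.store)
        assert len(table) == 1
        assert int(table.iloc[0]["target_concept_id"]) == 36770058

    def test_one_to_many_code_expands_rows(self, vocab_fixture):
        store = vocab_fixture.store
        multi = next(
            c for c in store.concepts.values()
            if c.vocabulary_id == "OPS" and len(store._maps_to.get(c.concept_id, [])) > 1
        )
        expr = _expr(multi.concept_code, item="OPS", category="surgery", vocab="OPS")
        table = build_source_to_standard([expr], store)
        expected = sorted(store._maps_to[multi.concept_id])
        assert list(table["target_concept_id"]) == expected
        assert len(table) >= 2


class TestSuggestion:
    def test_exact_name_ranks_first_with_score_one(self, vocab_fixture):
        ranked = suggest_candidates(vocab_fixture.store, "Cisplatin", k=5)
        assert ranked[0][0].concept_name == "Cisplatin"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_bag_of_words_symmetry(self, vocab_fixture):
        a = suggest_candidates(vocab_fixture.store, "neoplasm malignant lung", k=10)
        b = suggest_candidates(vocab_fixture.store, "lung malignant neoplasm", k=10)
        assert [(c.concept_id, pytest.approx(s)) for c, s in a] == [
            (c.concept_id, pytest.approx(s)) for c, s in b
        ]

    def test_empty_query_raises(self, vocab_fixture):
        with pytest.raises(ValueError):
            suggest_candidates(vocab_fixture.store, "###", k=3)

    def test_ranking_equals_exhaustive_cosine_scoring(self, vocab_fixture):
        """Oracle: score every concept with numpy and check the ranking.

        Floating-point near-ties between independent cosine computations
        make exact list equality brittle, so the check is: every returned
        score equals the exhaustively computed one, the ranking is
        non-increasing (exact ties broken by ascending concept_id), and
        no omitted concept outscores the returned cutoff.
        """
        store = vocab_fixture.store
        concepts = sorted(store.concepts.values(), key=lambda c: c.concept_id)
        names = [c.concept_name for c in concepts]
        vec = TfidfVectorizer(lowercase=True, token_pattern=r"(?u)\b\w+\b")
        m = vec.fit_transform(names).toarray()
        for query in ("breast neoplasm", "procedure thorax", "remission"):
            q = vec.transform([query]).toarray()[0]
            denom = np.linalg.norm(m, axis=1) * np.linalg.norm(q)
            scores = np.where(denom > 0, m @ q / np.where(denom == 0, 1, denom), 0.0)
            score_of = {c.concept_id: s for c, s in zip(concepts, scores)}
            got = suggest_candidates(store, query, k=8)
            assert len(got) == 8
            for concept, score in got:
                assert score == pytest.approx(score_of[concept.concept_id], abs=1e-9)
            for (c1, s1), (c2, s2) in zip(got, got[1:]):
                assert s1 >= s2 - 1e-9
                if s1 == s2:
                    assert c1.concept_id < c2.concept_id
            cutoff = got[-1][1]
            returned = {c.concept_id for c, _ in got}
            for cid, s in score_of.items():
                if cid not in returned:
                    assert s <= cutoff + 1e-9


class TestStatusSummary:
    def test_overall_percentages_on_reported_census(self):
        """16,946 / 746 / 52 / 96 of 17,840 expressions."""
        records = []
        counts = {"automatic": 16_946, "manual": 746, "etl": 52, "not_mappable": 96}
        i = 0
        for status, n in counts.items():
            for _ in range(n):
                targets = (1,) if status in ("automatic", "manual") else ()
                records.append(
                    MappingRecord(("diagnosis", "item", f"c{i}"), status, targets)
                )
                i += 1
        summary = summarize_statuses(records)
        overall = summary[summary["category"] == "overall"].set_index("status")
        assert overall.loc["automatic", "pct"] == 94.99
        assert overall.loc["manual", "pct"] == 4.18
        assert overall.loc["etl", "pct"] == 0.29
        assert overall.loc["mappable", "pct"] == 99.46
        assert int(overall.loc["mappable", "count"]) == 17_744

    def test_single_status_is_one_hundred_percent(self):
        records = [
            MappingRecord(("death", "item", f"c{i}"), "etl") for i in range(7)
        ]
        summary = summarize_statuses(records)
        row = summary[(summary["category"] == "death") & (summary["status"] == "etl")]
        assert row.iloc[0]["pct"] == 100.0

    def test_random_fixture_matches_direct_division(self):
        rng = np.random.default_rng(11)
        statuses = ["automatic", "manual", "etl", "not_mappable"]
        records = []
        for i in range(500):
            status = statuses[int(rng.integers(0, 4))]
            targets = (1,) if status in ("automatic", "manual") else ()
            category = ["diagnosis", "surgery", "course"][int(rng.integers(0, 3))]
            records.append(MappingRecord((category, "item", f"c{i}"), status, targets))
        summary = summarize_statuses(records)
        for category in ("diagnosis", "surgery", "course", "overall"):
            subset = [r for r in records if category in ("overall", r.source[0])]
            block = summary[summary["category"] == category].set_index("status")
            for status in statuses:
                n = sum(1 for r in subset if r.status == status)
                assert int(block.loc[status, "count"]) == n
                assert block.loc[status, "pct"] == pytest.approx(
                    round(100 * n / len(subset), 2), abs=0.01
                )
            statuses_sum = sum(block.loc[s, "pct"] for s in statuses)
            assert statuses_sum == pytest.approx(100.0, abs=0.03)
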