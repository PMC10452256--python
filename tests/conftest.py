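import datetime as dt
from pathlib import Path

import pandas as pd
import pytest

from oncomop.cli import run_pipeline
from oncomop.config import PipelineConfig
from oncomop.synthetic_data import (
    GeneratorConfig,
    generate_registry,
    generate_vocabulary_fixture,
)
from oncomop.vocabulary_store import load_vocabulary

VOCAB_HEADER = [
    "concept_id", "concept_name", "domain_id", "vocabulary_id",
    "concept_class_id", "standard_concept", "concept_code",
    "valid_start_date", "valid_end_date", "invalid_reason",
]
REL_HEADER = [
    "concept_id_1", "concept_id_2", "relationship_id",
    "valid_start_date", "valid_end_date", "invalid_reason",
]


def write_vocab(directory: Path, concepts, relationships):
    """Write hand-rolled concept/edge tuples in the tab-delimited dialect.

    concepts: (id, name, domain, vocab, class, std, code[, start, end])
    relationships: (c1, c2, rel[, start, end])
    """
    directory.mkdir(parents=True, exist_ok=True)
    c_rows = []
    for c in concepts:
        c = list(c)
        if len(c) == 7:
            c += ["20100101", "20991231"]
        c_rows.append(dict(zip(VOCAB_HEADER, c + [""])))
    r_rows = []
    for r in relationships:
        r = list(r)
        if len(r) == 3:
            r += ["20100101", "20991231"]
        r_rows.append(dict(zip(REL_HEADER, r + [""])))
    pd.DataFrame(c_rows, columns=VOCAB_HEADER).to_csv(
        directory / "CONCEPT.csv", sep="\t", index=False)
    pd.DataFrame(r_rows, columns=REL_HEADER).to_csv(
        directory / "CONCEPT_RELATIONSHIP.csv", sep="\t", index=False)
    return directory


def write_flat_file(directory: Path, name: str, rows: list[dict], columns: list[str]):
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=columns).to_csv(directory / f"{name}.csv", index=False)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=7, n_patients=60)


@pytest.fixture(scope="session")
def vocab_fixture(gen_config, tmp_path_factory):
    return generate_vocabulary_fixture(gen_config, tmp_path_factory.mktemp("vocab"))


@pytest.fixture(scope="session")
def registry_bundle(gen_config, vocab_fixture, tmp_path_factory):
    return generate_registry(gen_config, vocab_fixture, tmp_path_factory.mktemp("registry"))


@pytest.fixture(scope="session")
def pipeline_config(vocab_fixture, registry_bundle, tmp_path_factory):
    return PipelineConfig(
        vocab_dir=vocab_fixture.directory,
        source_dir=registry_bundle.directory,
        manual_mapping_file=vocab_fixture.manual_table_path,
        regimen_reference=vocab_fixture.regimen_reference_path,
        out_dir=tmp_path_factory.mktemp("out"),
        seed=7,
    )


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    return run_pipeline(pipeline_config)
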