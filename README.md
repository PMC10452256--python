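# oncomop

Harmonize German cancer-registry reporting data (oBDS-shaped flat
files) into the [OMOP CDM v5.4](https://ohdsi.github.io/CommonDataModel/)
with its oncology extension.

German state cancer registries collect diagnostics, treatments,
progression and follow-up per the national *oncological basis dataset*
(oBDS): reports organized into categories (diagnosis, surgery, systemic
therapy, ...), items (ICD-10-GM, OPS, side localization, ...) and
expressions — the concrete codes or free-text values.  Heterogeneous
documentation software makes the data syntactically uniform but
semantically ambiguous.  Mapping it onto the OMOP standardized
vocabularies yields a patient-centric relational model on which
federated, cross-registry analyses run unchanged.

`oncomop` is the pipeline for that harmonization, aimed at registry
informaticians and OHDSI implementers:

- **vocabulary_store** — loads tab-delimited CONCEPT /
  CONCEPT_RELATIONSHIP exports (Athena dialect), resolves source codes
  to standard concepts over valid `Maps to` edges (one-to-many
  resolutions kept in full), and censuses the relationship graph.
- **metadata_mapper** — classifies every oBDS expression as
  *automatic* (vocabulary-resolvable), *manual* (curated
  source_to_concept row), *etl* (dates and direct columns) or *not
  mappable*; builds the source_to_standard look-up table; suggests
  mapping candidates by TF-IDF cosine similarity over concept names
  (Usagi-style); summarizes status proportions.
- **substance_normalizer** — cleans free-text substance strings with an
  ordered, overridable regex rule set and matches cleaned names to
  standard drug concepts (RxNorm, via ATC synonyms where needed).
- **regimen_finder** — derives named treatment regimens by aggregating
  each patient's drug ingredients over trailing 30-day windows and
  subset-matching against a HemOnc-style regimen → ingredient
  reference; the largest matching ingredient set wins.
- **etl_core** — imports the registry's patient-centric "best-of" flat
  files, dates every clinical event through a fallback chain (own date
  → parent therapy start → tumor diagnosis date), constructs one visit
  per (person, day), and populates the CDM domain tables; unmappable
  codes survive as `concept_id = 0` rows with their source value.
- **episode_builder** — abstracts rows into oncology-extension
  episodes: treatment blocks (gap rule), disease dynamics (remission
  status), disease extent (TNM assessments) and regimen eras, each
  linked to its constituent events via `episode_event`.
- **qa_reporting** — per-item mapping rates (`100·n_target/n_source`,
  legitimately >100 % under one-to-many mappings) and a fixed core of
  Achilles-style logical checks (events after death / before birth,
  foreign concepts, orphan visits and links, unmapped-rate threshold).
- **synthetic_data** — generates a miniature vocabulary and a
  lung/breast (C34/C50) registry cohort with a ground-truth ledger, so
  the whole pipeline is testable without restricted registry data or a
  licensed vocabulary download.

## Worked example

Generate fixtures and run the full pipeline:

```sh
oncomop gen-fixtures --out-dir demo --seed 1 --n-patients 100
oncomop run-all \
    --vocab-dir demo/vocab --source-dir demo/registry \
    --manual-mapping-file demo/vocab/source_to_concept.csv \
    --regimen-reference demo/vocab/regimen_ingredients.csv \
    --out-dir demo/omop
```

prints

```
persons: 100
cdm.condition_occurrence: 128 rows
cdm.death: 15 rows
cdm.drug_exposure: 184 rows
cdm.measurement: 100 rows
cdm.observation: 649 rows
cdm.person: 100 rows
cdm.procedure_occurrence: 162 rows
cdm.visit_occurrence: 537 rows
episodes: 512
regimen assignments: 60
QA: no findings
```

All 100 synthetic patients transfer; 537 visits are constructed from
the distinct (person, day) pairs of the event list; 512 episodes and 60
regimen eras are derived; no logical check fires.  The per-item mapping
report (`demo/omop/item_report.csv`) shows the three characteristic
regimes:

```
            item               domain  n_source  n_target  mapping_rate_pct
       ICD-10-GM condition_occurrence       100       100            100.00
      Laterality          observation       100        89             89.00
             OPS procedure_occurrence       103       135            131.07
```

ICD-10-GM resolves completely; laterality stays below 100 % because the
oBDS values "U" (unknown) and "B" (both sides) have no standard-concept
representation and are kept as `concept_id = 0` rows; OPS exceeds 100 %
because some procedure codes map one-to-many into SNOMED, expanding one
source row into several target rows.

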