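# Methods

This note documents the models, rules and numerical choices behind
`oncomop`, and what the synthetic test bed does and does not
demonstrate.

## Vocabulary model and standard resolution

A vocabulary export is a concept table (id, name, domain, vocabulary,
class, standard flag, code, validity dates) and a relationship edge
table.  Resolution of a source code to its standard representation
follows the OMOP convention: only `Maps to` edges map; `Subsumes`,
`Mapped from`, `Asso morph of` and the rest are retained solely for the
relationship census.  A code may resolve to nothing (not mappable), to
one concept, or to several (one-to-many, typical for OPS procedure
codes); one-to-many results are always returned in full and expanded
explicitly downstream — this is what lets a per-item mapping rate
exceed 100 %.

Edge validity is judged against a *reference date*, defaulting to the
latest `valid_start_date` in the concept file: an edge counts only if
its `valid_end_date` is on or after it.  Athena exports keep deprecated
edges, and silently honoring them would resurrect retired mappings.
Code look-up is exact and case-sensitive on `(vocabulary_id,
concept_code)`; an unknown code raises a distinct error rather than
returning an empty result, because "we have never seen this code" and
"this code has no standard concept" demand different operator
reactions.

The census counts each valid edge once per anchoring endpoint
(`concept_id_1`) inside the queried concept set, grouped by
relationship and by the anchor's oBDS category; shares are percentages
of the grand total, half-up to one decimal.

## Expression classification

Every oBDS expression receives exactly one status with precedence
**automatic > manual > etl > not_mappable**.  The precedence is a
design choice (the classification scheme itself does not define
overlap behavior): a community-maintained vocabulary mapping is
preferred over a locally curated one because it is versioned, reviewed
and shared across sites.  A manual-review row with target concept 0
marks an expression a curator examined and declared unmappable; it is
classified not_mappable, preventing endless re-review.  Date items and
declared direct-column items are `etl`: they move structurally during
the load and need no concept.

Candidate suggestion for manual mapping uses TF-IDF over lowercase word
unigrams of concept names with smoothed IDF and cosine similarity,
ties broken by ascending concept id.  Unigram bag-of-words is
deliberate: concept names are short noun phrases, and the method is a
ranking aid for a human curator, not an auto-mapper.

Status percentages are rounded half-up to two decimals; census shares
to one decimal.  Half-up (not banker's) rounding is the registry
reporting convention and is applied uniformly through one helper.

## Substance cleaning and drug matching

Free-text substance fields carry dosages ("75mg/m2", "AUC5"),
schedules, parentheticals, trade symbols and several drugs joined by
`+ / , und`.  Cleaning applies an ordered list of (regex, replacement)
rules — shipped as a YAML file (`oncomop/data/substance_rules.yaml`)
that registries can override, since free-text habits differ per site —
then splits on the separators, lowercases, collapses whitespace and
deduplicates.  Dosage stripping runs before splitting so the `/` in
"mg/m2" never splits a name; bare numbers glued to hyphens survive so
"5-fluorouracil" stays intact.  Cleaning is idempotent.

Matching is an exact case-insensitive comparison of the cleaned name
against Drug-domain concept names, followed by `Maps to` resolution (so
a non-standard ATC name lands on its RxNorm ingredient).  There is no
fuzzy fallback: a miss stays an explicit unmapped marker carrying the
source value.  This loses data by construction — the mapped count can
never exceed the mention count — which is the accepted price for
precision; NLP-based recovery is out of scope.

## Regimen derivation

Drug exposures are aggregated per patient over a trailing window of
`window_days` (default 30) anchored at every exposure date.  A
reference regimen matches a window when its complete ingredient set is
a subset of the window's set; among matches the largest ingredient set
wins, ties broken by ascending regimen concept id; same-regimen
assignments with overlapping windows merge into one era.  Subset (not
exact-set) matching tolerates concomitant supportive drugs; the
largest-set preference prevents a combination course from being
reported as one of its component monotherapies.  The merge rule is a
deliberate design decision (consecutive anchors within one course
should not multiply eras) and `window_days` is configurable for
sensitivity analysis.  The derivation is deterministic and
translation-invariant, and is tested for equivalence against an
exhaustive window-enumeration oracle.

## ETL: event dating, visits, population

Registries record no encounters, so visits are constructed: every
clinical record is dated through the fallback chain *own date → parent
systemic-therapy start date → diagnosis date of its tumor*; records
with no resolvable date are excluded and counted.  All events of one
person on one day share a single visit; visit keys are assigned in
(person, date) order, which makes the ETL deterministic and re-runs
byte-identical.

Partial dates — common in registries — are imputed to mid-period
(July 1 for a bare year, the 15th for year-month) and flagged in a
companion `*_imputed` column, keeping events orderable without
discarding provenance.  Unparseable date cells quarantine the row with
a per-row diagnostic instead of aborting the file.

Identifying fields (names, addresses, registry ids) are dropped at
import; they never reach the CDM.  Routing is a declarative table from
oBDS item to OMOP domain (ICD-10-GM → condition, OPS → procedure,
TNM → observation, ICD-O-3 topography → measurement, substances → drug,
CTCAE → condition, remission status → observation); an item routed to
an undeclared domain fails fast with the item name.  Each source row
emits `max(1, n_resolved)` target rows: resolved concepts expand,
unresolved codes emit one `concept_id = 0` row whose source value
preserves the original code.  All rows carry a single registry
provenance type concept (32879).

## Episodes

- *Treatment*: per (person, modality, block), where a block chains
  same-modality events with gaps ≤ `gap_days` (default 30, matching
  the regimen window; a month without therapy plausibly separates
  courses).  Surgeries are single-day episodes.
- *Disease dynamic*: one episode per follow-up assessment; the object
  concept is the mapped remission state, 0 when unmappable.
- *Disease extent*: one episode per (person, tumor, staging date),
  linked to the contributing T/N/M rows.
- *Regimen*: one-to-one with the regimen finder's assignments, spanning
  the contributing exposures.
- *Overall disease* parent episodes (first diagnosis → last event) are
  available behind a config flag, default off.

Every episode links ≥ 1 event through `episode_event`; spans always lie
within the union of linked event dates.

## QA checks

Six built-in checks: events after death, events before birth year,
non-zero concepts absent from the vocabulary store, visits without
persons, dangling episode-event links, and a per-table unmapped-rate
threshold (default 0.5).  The first five are `error` severity — they
indicate a defective load.  The unmapped-rate check is a `warning`:
unmappable source codes are expected, quantified information loss of
the harmonization, not a run defect.  Each check reports the exact
offending-row count, and the test suite verifies planted-defect
recovery (d planted defects ⇒ a finding of count exactly d).

## Synthetic test bed

The generator produces ~250 vocabulary concepts and a C34/C50 cohort
first diagnosed 2016 or later.  Defaults: 300 patients, even C34/C50
mix, 10 % unmappable laterality values ("U"/"B"), 30 % free-text noise
on substance mentions (dosage suffixes, casing, parentheticals,
separator variation), 25 % of OPS codes with one-to-many mappings.
Regimen courses are planted so that every ingredient is administered on
the course start date with all administrations inside 20 days, and
courses of one patient at least 61 days apart — under these conditions
the trailing-window matcher provably recovers exactly the planted
regimens, so ledger equality is a meaningful oracle rather than a
tautology.  Off-regimen courses (hormone and other monotherapies absent
from the reference) are planted alongside to exercise the no-match
path.

The ledger records every planted code's true resolution and every
planted course; integration tests assert exact recovery and a QA-clean
run.  What this shows: the mapping, ETL, windowing and episode logic
are internally correct.  What it does not show: performance on real
registry free text (richer misspellings, protocol names), realistic
incidence/survival structure, multi-institution duplicate resolution,
or behavior under vocabulary releases with conflicting mappings —
real-data mapping rates will be lower than the synthetic ones.

## Problem sizes

Unit and property tests run on stores of ≤ 300 concepts and registries
of ≤ 60 patients; the end-to-end acceptance path uses 200 patients and
the acceptance script 300, sizes at which every stage completes in
seconds while exercising all code paths (one-to-many expansion,
unmappable codes, partial dates, merged regimen eras, deaths).

## Known limitations

- Visit construction is purely date-based; true encounters, transfers
  and providers are not modeled.
- The event-date fallback chain is a fixed two-step rule; registries
  with richer linkage may need additional steps.
- Substance matching is exact-name only; no spelling correction, dose
  or route extraction.
- Episode building does not number therapy lines or count cycles.
- Storage is in-memory pandas with CSV round-trips, sized for registry
  extracts in the hundreds of thousands of rows, not for streaming
  million-patient loads.
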