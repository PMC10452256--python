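"""Generate a miniature vocabulary and registry flat files with ground truth.

Real registry extracts are access-restricted and the full standardized
vocabularies need a licensed download, so every pipeline stage is
exercised against synthetic stand-ins:

* a vocabulary fixture of a few hundred concepts spanning the source
  vocabularies a German registry actually reports (ICD-10-GM, ICD-O-3,
  OPS, TNM, CTCAE, free-text substances against RxNorm/ATC, Cancer
  Modifier laterality) with ``Maps to`` chains, one-to-many procedure
  mappings, deprecated edges, ``Subsumes``/``Mapped from`` edges for
  census tests, and a HemOnc-style regimen → ingredient reference;
* patient-centric "best-of" flat files for a lung/breast (C34/C50)
  cohort first diagnosed 2016 or later: diagnoses with ICD-10-GM,
  ICD-O-3 and TNM, surgeries with OPS codes, systemic therapy with
  noisy free-text substances, radiation, follow-up remission status,
  CTCAE side effects, laterality including the unmappable "U"/"B"
  values, and deaths.

Alongside the flat files a *ground-truth ledger* records every planted
code's true concept resolution and every planted regimen course, so
integration tests assert exact recovery instead of comparing against
any real-data count.  Everything is deterministic per seed.

The generator emulates coding structure, not epidemiology: incidence,
survival and co-occurrence patterns are uniform draws, so passing the
end-to-end suite demonstrates pipeline correctness, not clinical
realism.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metadata_mapper import SOURCE_TO_CONCEPT_COLUMNS, SourceExpression
from .vocabulary_store import VocabularyStore, load_vocabulary

__all__ = [
    "GeneratorConfig",
    "VocabularyFixture",
    "RegistryBundle",
    "generate_vocabulary_fixture",
    "generate_registry",
    "build_expressions",
]

LATERALITY_CONCEPTS = {"R": 36770058, "L": 36770232, "M": 36770562}
UNMAPPABLE_LATERALITY = ("U", "B")

_INGREDIENTS = [
    "Cisplatin", "Carboplatin", "Etoposide", "Paclitaxel", "Docetaxel",
    "Doxorubicin", "Epirubicin", "Cyclophosphamide", "Gemcitabine",
    "Vinorelbine", "Pemetrexed", "5-Fluorouracil", "Methotrexate",
    "Trastuzumab", "Pertuzumab", "Tamoxifen", "Letrozole", "Anastrozole",
    "Bevacizumab", "Irinotecan", "Topotecan", "Ifosfamide", "Mitomycin",
    "Capecitabine",
]

# regimen name -> ingredient names; sets are pairwise distinct and no
# unregimented drug (see _OFF_REGIMEN) appears in any of them
_REGIMENS = {
    "Cisplatin and Etoposide": ("Cisplatin", "Etoposide"),
    "Carboplatin and Etoposide": ("Carboplatin", "Etoposide"),
    "Carboplatin and Paclitaxel": ("Carboplatin", "Paclitaxel"),
    "Cisplatin and Pemetrexed": ("Cisplatin", "Pemetrexed"),
    "Cisplatin and Vinorelbine": ("Cisplatin", "Vinorelbine"),
    "Gemcitabine and Cisplatin": ("Gemcitabine", "Cisplatin"),
    "Doxorubicin and Cyclophosphamide": ("Doxorubicin", "Cyclophosphamide"),
    "Epirubicin and Cyclophosphamide": ("Epirubicin", "Cyclophosphamide"),
    "CMF": ("Cyclophosphamide", "Methotrexate", "5-Fluorouracil"),
    "Trastuzumab Pertuzumab and Docetaxel": ("Trastuzumab", "Pertuzumab", "Docetaxel"),
    "Docetaxel monotherapy": ("Docetaxel",),
    "Paclitaxel monotherapy": ("Paclitaxel",),
}

# therapies planted without any matching reference regimen
_OFF_REGIMEN = ["Bevacizumab", "Tamoxifen", "Letrozole", "Anastrozole", "Mitomycin"]

_MORPHOLOGIES = ["8140/3", "8070/3", "8041/3", "8046/3", "8500/3", "8520/3", "8522/3"]
_REMISSION = {
    "V": "Complete remission",
    "T": "Partial remission",
    "K": "Stable disease",
    "P": "Progressive disease",
}
_CTCAE = {
    "ANE": "Anemia",
    "NAU": "Nausea",
    "NEU": "Peripheral neuropathy",
    "FAT": "Fatigue",
    "ALO": "Alopecia",
}
_RADIATION = {"PERK": "Percutaneous radiotherapy", "BRACHY": "Brachytherapy"}
_TNM_T = ["cT1", "cT2", "cT3", "cT4"]
_TNM_N = ["cN0", "cN1", "cN2", "cN3"]
_TNM_M = ["cM0", "cM1"]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic registry.

    Defaults emulate a lung/breast registry extract: an even C34/C50
    mix, first diagnoses from 2016 on, roughly one in ten laterality
    values unmappable ("U"/"B"), free-text substance noise on about a
    third of mentions, and one in four OPS codes carrying a
    one-to-many vocabulary mapping.
    """

    seed: int = 0
    n_patients: int = 300
    entity_mix: dict[str, float] = field(default_factory=lambda: {"C34": 0.5, "C50": 0.5})
    date_start: dt.date = dt.date(2016, 1, 1)
    date_end: dt.date = dt.date(2021, 12, 31)
    report_intensity: float = 1.0  # scales per-patient event counts
    unmappable_code_rate: float = 0.1
    free_text_noise_rate: float = 0.3
    one_to_many_rate: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.entity_mix.values()) - 1.0) > 1e-9:
            raise ValueError("entity mix proportions must sum to 1")
        for name in ("unmappable_code_rate", "free_text_noise_rate", "one_to_many_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Vocabulary fixture
# ---------------------------------------------------------------------------

_VALID = ("20100101", "20991231")


@dataclass
class VocabularyFixture:
    directory: Path
    store: VocabularyStore
    regimen_reference_path: Path
    manual_table_path: Path
    ingredient_ids: dict[str, int]
    regimen_ids: dict[str, int]


def _concept_row(cid, name, domain, vocab, cls, standard, code,
                 valid=("20100101", "20991231")):
    return {
        "concept_id": cid,
        "concept_name": name,
        "domain_id": domain,
        "vocabulary_id": vocab,
        "concept_class_id": cls,
        "standard_concept": standard,
        "concept_code": code,
        "valid_start_date": valid[0],
        "valid_end_date": valid[1],
        "invalid_reason": "",
    }


def _edge(c1, c2, rel, valid=("20100101", "20991231")):
    return {
        "concept_id_1": c1,
        "concept_id_2": c2,
        "relationship_id": rel,
        "valid_start_date": valid[0],
        "valid_end_date": valid[1],
        "invalid_reason": "",
    }


def generate_vocabulary_fixture(
    config: GeneratorConfig, directory: str | Path
) -> VocabularyFixture:
    """Write CONCEPT/CONCEPT_RELATIONSHIP files plus look-up tables.

    Byte-identical per seed.  The laterality concepts R/L/M carry their
    real Cancer Modifier concept_ids; a slice of OPS codes (the
    ``one_to_many_rate`` fraction, rounded) gets two ``Maps to``
    targets; a handful of deprecated edges exercise validity filtering.
    """
    rng = np.random.default_rng(config.seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    concepts: list[dict] = []
    edges: list[dict] = []

    def maps_to(src, dst):
        edges.append(_edge(src, dst, "Maps to"))
        edges.append(_edge(dst, src, "Mapped from"))

    # SNOMED parents + per-subcode condition concepts; ICD-10-GM and
    # ICD-O-3 topography codes map onto them / onto site concepts
    parents = {"C34": 4400001, "C50": 4400002}
    concepts.append(_concept_row(4400001, "Malignant neoplasm of lung", "Condition",
                                 "SNOMED", "Clinical Finding", "S", "363358000"))
    concepts.append(_concept_row(4400002, "Malignant neoplasm of breast", "Condition",
                                 "SNOMED", "Clinical Finding", "S", "363346000"))
    i = 0
    for entity, n_sub in (("C34", 10), ("C50", 10)):
        for sub in range(n_sub):
            code = f"{entity}.{sub}"
            snomed = 4410000 + i
            icd = 45500000 + i
            site = 4420000 + i
            topo = 44790000 + i
            concepts.append(_concept_row(
                snomed, f"Malignant neoplasm of {entity} subsite {sub}",
                "Condition", "SNOMED", "Clinical Finding", "S", f"3633{i:02d}00"))
            concepts.append(_concept_row(
                icd, f"ICD-10-GM {code}", "Condition", "ICD10GM", "ICD10 code", "", code))
            concepts.append(_concept_row(
                site, f"Structure of {entity} subsite {sub}", "Spec Anatomic Site",
                "SNOMED", "Body Structure", "S", f"1812{i:02d}00"))
            concepts.append(_concept_row(
                topo, f"Topography {code}", "Measurement", "ICDO3", "ICDO Topography", "", code))
            maps_to(icd, snomed)
            maps_to(topo, site)
            edges.append(_edge(parents[entity], snomed, "Subsumes"))
            i += 1

    # ICD-O-3 morphologies -> SNOMED morphologic abnormalities
    for j, code in enumerate(_MORPHOLOGIES):
        morph_std = 4430000 + j
        morph_src = 44800000 + j
        concepts.append(_concept_row(
            morph_std, f"Morphologic abnormality {code}", "Observation",
            "SNOMED", "Morph Abnormality", "S", f"4430{j:02d}"))
        concepts.append(_concept_row(
            morph_src, f"ICD-O-3 morphology {code}", "Observation",
            "ICDO3", "ICDO Histology", "", code))
        maps_to(morph_src, morph_std)
        # census-only morphology association back to a condition concept
        edges.append(_edge(morph_std, 4410000 + (j % i), "Asso morph of"))

    # OPS procedure codes; a deterministic slice gets two Maps to edges
    n_ops = 30
    n_multi = int(round(config.one_to_many_rate * n_ops))
    multi_idx = set(rng.choice(n_ops, size=n_multi, replace=False).tolist())
    ops_codes = []
    for j in range(n_ops):
        code = f"5-{300 + j}.{j % 10}"
        ops_codes.append(code)
        src = 46000000 + j
        dst = 4440000 + 2 * j
        concepts.append(_concept_row(
            src, f"OPS procedure {code}", "Procedure", "OPS", "Procedure", "", code))
        concepts.append(_concept_row(
            dst, f"Surgical procedure {j} on thorax or breast", "Procedure",
            "SNOMED", "Procedure", "S", f"3870{j:02d}"))
        maps_to(src, dst)
        if j in multi_idx:
            dst2 = 4440000 + 2 * j + 1
            concepts.append(_concept_row(
                dst2, f"Reconstruction procedure {j}", "Procedure",
                "SNOMED", "Procedure", "S", f"3871{j:02d}"))
            maps_to(src, dst2)

    # TNM staging values -> Cancer Modifier standard concepts
    for j, code in enumerate(_TNM_T + _TNM_N + _TNM_M):
        src = 47000000 + j
        dst = 36760000 + j
        concepts.append(_concept_row(
            src, f"TNM category {code}", "Measurement", "TNM", "Staging", "", code))
        concepts.append(_concept_row(
            dst, f"AJCC {code} category", "Measurement", "Cancer Modifier",
            "Staging/Grading", "S", code.lower()))
        maps_to(src, dst)

    # laterality: the three mappable Cancer Modifier concepts
    for code, cid in LATERALITY_CONCEPTS.items():
        side = {"R": "right", "L": "left", "M": "midline"}[code]
        concepts.append(_concept_row(
            cid, f"Tumor laterality {side}", "Observation", "Cancer Modifier",
            "Topography", "S", code))

    # drugs: RxNorm standard ingredients, a few non-standard ATC names
    ingredient_ids: dict[str, int] = {}
    for j, name in enumerate(_INGREDIENTS):
        cid = 1300000 + j
        ingredient_ids[name] = cid
        concepts.append(_concept_row(
            cid, name, "Drug", "RxNorm", "Ingredient", "S", f"rx{j:04d}"))
    for j, name in enumerate(_INGREDIENTS[:8]):
        atc = 21600000 + j
        concepts.append(_concept_row(
            atc, f"{name.lower()}; parenteral", "Drug", "ATC", "ATC 5th", "", f"L01X{j:02d}"))
        maps_to(atc, ingredient_ids[name])

    # HemOnc-style regimen concepts + ingredient reference
    regimen_ids: dict[str, int] = {}
    reference_rows = []
    for j, (name, ingredients) in enumerate(_REGIMENS.items()):
        rid = 35800000 + j
        regimen_ids[name] = rid
        concepts.append(_concept_row(
            rid, name, "Regimen", "HemOnc", "Regimen", "S", f"ho{j:03d}"))
        for ing in ingredients:
            reference_rows.append(
                {"regimen_concept_id": rid, "ingredient_concept_id": ingredient_ids[ing]}
            )

    # remission statuses -> SNOMED
    for j, (code, label) in enumerate(_REMISSION.items()):
        src = 48000000 + j
        dst = 4450001 + j
        concepts.append(_concept_row(
            dst, label, "Observation", "SNOMED", "Clinical Finding", "S", f"2680{j:02d}"))
        concepts.append(_concept_row(
            src, f"Follow-up status {code}", "Observation", "OBDS-FOLLOWUP",
            "Answer", "", code))
        maps_to(src, dst)

    # CTCAE side effects -> MedDRA
    for j, (code, label) in enumerate(_CTCAE.items()):
        src = 49000000 + j
        dst = 35200000 + j
        concepts.append(_concept_row(
            dst, label, "Condition", "MedDRA", "PT", "S", f"md{j:04d}"))
        concepts.append(_concept_row(
            src, f"CTCAE {label}", "Condition", "CTCAE", "Term", "", code))
        maps_to(src, dst)

    # radiation types have no vocabulary coverage: manual review table
    manual_rows = []
    for j, (code, label) in enumerate(_RADIATION.items()):
        src = 50000000 + j
        dst = 4460001 + j
        concepts.append(_concept_row(
            dst, label, "Procedure", "SNOMED", "Procedure", "S", f"1081{j:02d}"))
        concepts.append(_concept_row(
            src, f"oBDS radiation {code}", "Procedure", "OBDS-RADIATION", "Type", "", code))
        manual_rows.append(
            {
                "source_code": code,
                "source_vocabulary_id": "OBDS-RADIATION",
                "source_code_description": label,
                "target_concept_id": dst,
                "valid_start_date": _VALID[0],
                "valid_end_date": _VALID[1],
                "invalid_reason": "",
            }
        )

    # a reviewed-but-unmappable marker row (target 0)
    manual_rows.append(
        {
            "source_code": "X",
            "source_vocabulary_id": "OBDS-RADIATION",
            "source_code_description": "Other radiation, reviewed, no concept",
            "target_concept_id": 0,
            "valid_start_date": _VALID[0],
            "valid_end_date": _VALID[1],
            "invalid_reason": "",
        }
    )

    # deprecated edges (valid_to before the reference date) that must
    # never influence resolution; anchor the reference date itself with
    # a late-starting bookkeeping concept
    concepts.append(_concept_row(
        4499999, "Vocabulary release anchor", "Metadata", "SNOMED", "Metadata",
        "S", "release-anchor", valid=("20230101", "20991231")))
    edges.append(_edge(45500000, 4410001, "Maps to", valid=("20100101", "20150101")))
    edges.append(_edge(46000000, 4440002, "Maps to", valid=("20100101", "20150101")))

    concept_frame = pd.DataFrame(concepts).sort_values("concept_id")
    edge_frame = pd.DataFrame(edges).sort_values(
        ["concept_id_1", "concept_id_2", "relationship_id", "valid_end_date"]
    )
    concept_frame.to_csv(directory / "CONCEPT.csv", sep="\t", index=False)
    edge_frame.to_csv(directory / "CONCEPT_RELATIONSHIP.csv", sep="\t", index=False)

    reference_path = directory / "regimen_ingredients.csv"
    pd.DataFrame(reference_rows).sort_values(
        ["regimen_concept_id", "ingredient_concept_id"]
    ).to_csv(reference_path, index=False)

    manual_path = directory / "source_to_concept.csv"
    pd.DataFrame(manual_rows, columns=SOURCE_TO_CONCEPT_COLUMNS).to_csv(
        manual_path, index=False
    )

    return VocabularyFixture(
        directory=directory,
        store=load_vocabulary(directory),
        regimen_reference_path=reference_path,
        manual_table_path=manual_path,
        ingredient_ids=ingredient_ids,
        regimen_ids=regimen_ids,
    )


def build_expressions(store: VocabularyStore) -> list[SourceExpression]:
    """Derive the oBDS expression list exercised by the fixture.

    Every source-vocabulary code in the store becomes one expression;
    the unmappable laterality values "U"/"B", a few date items and
    patient-master-data fields are added explicitly.
    """
    vocab_slot = {
        "ICD10GM": ("diagnosis", "ICD-10-GM"),
        "OPS": ("surgery", "OPS"),
        "CTCAE": ("systemic therapy side effect", "CTCAE"),
        "OBDS-FOLLOWUP": ("course", "Remission status"),
        "OBDS-RADIATION": ("radiation", "Radiation type"),
        "Cancer Modifier": ("diagnosis", "Laterality"),
    }
    exprs: list[SourceExpression] = []
    for concept in sorted(store.concepts.values(), key=lambda c: c.concept_id):
        if concept.vocabulary_id == "ICDO3":
            item = "Morphology ICDO3" if "/" in concept.concept_code else "Topography ICDO3"
            exprs.append(SourceExpression("histology" if "/" in concept.concept_code else "diagnosis",
                                          item, concept.concept_code,
                                          concept.concept_name, "finite", "ICDO3"))
        elif concept.vocabulary_id == "TNM":
            kind = concept.concept_code[1].upper()
            exprs.append(SourceExpression("tnm classification", f"TNM-{kind}",
                                          concept.concept_code, concept.concept_name,
                                          "finite", "TNM"))
        elif concept.vocabulary_id in vocab_slot:
            if concept.vocabulary_id == "Cancer Modifier" and concept.concept_class_id != "Topography":
                continue  # TNM targets, not laterality expressions
            category, item = vocab_slot[concept.vocabulary_id]
            exprs.append(SourceExpression(category, item, concept.concept_code,
                                          concept.concept_name, "finite",
                                          concept.vocabulary_id))
    for code in UNMAPPABLE_LATERALITY:
        exprs.append(SourceExpression("diagnosis", "Laterality", code,
                                      {"U": "unknown", "B": "both sides"}[code],
                                      "finite", "Cancer Modifier"))
    for item in ("Diagnosis date", "Therapy start", "Death date"):
        exprs.append(SourceExpression("course", item, f"<{item.lower()}>", item, "date"))
    for code in ("name", "address"):
        exprs.append(SourceExpression("patient master data", "Identifying data",
                                      code, code, "free_text"))
    return exprs


# ---------------------------------------------------------------------------
# Registry flat files
# ---------------------------------------------------------------------------


@dataclass
class RegistryBundle:
    directory: Path
    tables: dict[str, pd.DataFrame]
    ledger_mappings: pd.DataFrame
    ledger_regimens: pd.DataFrame


def _noisy_name(rng: np.random.Generator, name: str, noise_rate: float) -> str:
    if rng.random() >= noise_rate:
        return name
    style = rng.integers(0, 4)
    if style == 0:
        return name.upper()
    if style == 1:
        return f"{name} {rng.integers(10, 200)}mg/m2"
    if style == 2:
        return f"{name} (weekly)"
    return f"{name} AUC{rng.integers(2, 7)}"


def generate_registry(
    config: GeneratorConfig,
    fixture: VocabularyFixture,
    directory: str | Path,
) -> RegistryBundle:
    """Write best-of flat files plus the ground-truth ledger.

    Regimen courses are planted so that every ingredient is
    administered on the course start date and all administrations fall
    within 20 days — therefore every trailing 30-day window over a
    course sees the full ingredient set and the planted regimen is
    exactly what subset matching recovers.  Courses of one patient are
    at least 61 days apart so windows never mix.
    """
    rng = np.random.default_rng(config.seed + 1)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    store = fixture.store

    entities = sorted(config.entity_mix)
    probs = np.array([config.entity_mix[e] for e in entities])
    span_days = (config.date_end - config.date_start).days

    rows: dict[str, list[dict]] = {
        name: [] for name in (
            "patient", "diagnosis", "surgery", "systemic_therapy", "substance",
            "radiation", "follow_up", "side_effect", "death",
        )
    }
    ledger_map: list[dict] = []
    ledger_reg: list[dict] = []

    def expected(vocabulary_id: str, code: str) -> list[int]:
        from .vocabulary_store import UnknownCodeError, resolve_to_standard

        try:
            return [c.concept_id for c in resolve_to_standard(store, (vocabulary_id, code))]
        except UnknownCodeError:
            return []

    manual_expected = {"PERK": [4460001], "BRACHY": [4460002]}
    regimen_names = sorted(_REGIMENS)
    sub_id = th_id = su_id = fu_id = se_id = ra_id = 0

    for pid in range(1, config.n_patients + 1):
        entity = entities[int(rng.choice(len(entities), p=probs))]
        sex = "F" if (entity == "C50" and rng.random() < 0.95) or rng.random() < 0.4 else "M"
        birth_year = int(rng.integers(1930, 1991))
        rows["patient"].append(
            {"patient_id": pid, "sex": sex, "birth_year": birth_year,
             "first_name": f"given{pid}", "last_name": f"family{pid}"}
        )

        dx_date = config.date_start + dt.timedelta(days=int(rng.integers(0, span_days - 400)))
        dx_id = f"D{pid:05d}"
        icd = f"{entity}.{int(rng.integers(0, 10))}"
        if rng.random() < config.unmappable_code_rate:
            laterality = UNMAPPABLE_LATERALITY[int(rng.integers(0, 2))]
        else:
            laterality = ["R", "L", "M"][int(rng.integers(0, 3))]
        morph = _MORPHOLOGIES[int(rng.integers(0, len(_MORPHOLOGIES)))]
        tnm = (
            _TNM_T[int(rng.integers(0, 4))],
            _TNM_N[int(rng.integers(0, 4))],
            _TNM_M[int(rng.integers(0, 2))],
        )
        rows["diagnosis"].append(
            {
                "diagnosis_id": dx_id, "patient_id": pid,
                "diagnosis_date": dx_date.isoformat(),
                "icd10gm": icd, "icdo3_topography": icd, "icdo3_morphology": morph,
                "laterality": laterality,
                "tnm_t": tnm[0], "tnm_n": tnm[1], "tnm_m": tnm[2],
                "tnm_date": dx_date.isoformat(),
            }
        )
        for item, vocab, code in (
            ("ICD-10-GM", "ICD10GM", icd),
            ("Topography ICDO3", "ICDO3", icd),
            ("Morphology ICDO3", "ICDO3", morph),
            ("Laterality", "Cancer Modifier", laterality),
            ("TNM-T", "TNM", tnm[0]),
            ("TNM-N", "TNM", tnm[1]),
            ("TNM-M", "TNM", tnm[2]),
        ):
            ledger_map.append(
                {"person_id": pid, "source_table": "diagnosis", "source_row_id": dx_id,
                 "item": item, "code": code,
                 "expected_concept_ids": ";".join(map(str, expected(vocab, code)))}
            )

        last_event = dx_date

        n_surgeries = int(rng.integers(0, max(2, round(3 * config.report_intensity))))
        for _ in range(n_surgeries):
            su_id += 1
            s_date = dx_date + dt.timedelta(days=int(rng.integers(10, 100)))
            j = int(rng.integers(0, 30))
            ops = f"5-{300 + j}.{j % 10}"
            sid = f"S{su_id:05d}"
            rows["surgery"].append(
                {"surgery_id": sid, "patient_id": pid, "diagnosis_id": dx_id,
                 "surgery_date": s_date.isoformat(), "ops_code": ops}
            )
            ledger_map.append(
                {"person_id": pid, "source_table": "surgery", "source_row_id": sid,
                 "item": "OPS", "code": ops,
                 "expected_concept_ids": ";".join(map(str, expected("OPS", ops)))}
            )
            last_event = max(last_event, s_date)

        # systemic therapy: regimen courses and off-regimen courses
        n_courses = 0
        if rng.random() < 0.6 * min(1.0, config.report_intensity + 0.2):
            n_courses = 1 + int(rng.random() < 0.25)
        course_start = dx_date + dt.timedelta(days=int(rng.integers(20, 60)))
        for course in range(n_courses):
            th_id += 1
            tid = f"T{th_id:05d}"
            on_regimen = rng.random() < 0.8
            if on_regimen:
                regimen_name = regimen_names[int(rng.integers(0, len(regimen_names)))]
                ingredients = list(_REGIMENS[regimen_name])
            else:
                ingredients = [_OFF_REGIMEN[int(rng.integers(0, len(_OFF_REGIMEN)))]]
            course_end = course_start + dt.timedelta(days=20)
            rows["systemic_therapy"].append(
                {"therapy_id": tid, "patient_id": pid, "diagnosis_id": dx_id,
                 "therapy_start": course_start.isoformat(),
                 "therapy_end": course_end.isoformat()}
            )
            # every ingredient on day 0; extra administrations within 20 days
            mentions: list[tuple[str, dt.date, list[str]]] = []
            combine = len(ingredients) >= 2 and rng.random() < 0.3
            if combine:
                sep = [" + ", " und ", "/"][int(rng.integers(0, 3))]
                text = sep.join(
                    _noisy_name(rng, n, config.free_text_noise_rate) for n in ingredients[:2]
                )
                mentions.append((text, course_start, ingredients[:2]))
                rest = ingredients[2:]
            else:
                rest = ingredients
            for name in rest:
                mentions.append(
                    (_noisy_name(rng, name, config.free_text_noise_rate), course_start, [name])
                )
            for name in ingredients:
                if rng.random() < 0.5:
                    extra = course_start + dt.timedelta(days=int(rng.integers(7, 21)))
                    mentions.append(
                        (_noisy_name(rng, name, config.free_text_noise_rate), extra, [name])
                    )
            for text, date, names in mentions:
                sub_id += 1
                sid = f"SU{sub_id:05d}"
                blank_date = date == course_start and rng.random() < 0.2
                rows["substance"].append(
                    {"substance_id": sid, "therapy_id": tid, "patient_id": pid,
                     "substance_text": text,
                     "administration_date": "" if blank_date else date.isoformat()}
                )
                ledger_map.append(
                    {"person_id": pid, "source_table": "substance", "source_row_id": sid,
                     "item": "Substances", "code": text,
                     "expected_concept_ids": ";".join(
                         str(fixture.ingredient_ids[n]) for n in names)}
                )
                last_event = max(last_event, date)
            if on_regimen:
                ledger_reg.append(
                    {"person_id": pid,
                     "regimen_concept_id": fixture.regimen_ids[regimen_name],
                     "course_start": course_start.isoformat()}
                )
            # side effect attached to this course
            if rng.random() < 0.4:
                se_id += 1
                sid = f"SE{se_id:05d}"
                code = sorted(_CTCAE)[int(rng.integers(0, len(_CTCAE)))]
                blank = rng.random() < 0.3
                onset = course_start + dt.timedelta(days=int(rng.integers(0, 15)))
                rows["side_effect"].append(
                    {"side_effect_id": sid, "therapy_id": tid, "patient_id": pid,
                     "ctcae_code": code, "ctcae_grade": int(rng.integers(1, 5)),
                     "onset_date": "" if blank else onset.isoformat()}
                )
                ledger_map.append(
                    {"person_id": pid, "source_table": "side_effect", "source_row_id": sid,
                     "item": "CTCAE", "code": code,
                     "expected_concept_ids": ";".join(map(str, expected("CTCAE", code)))}
                )
                last_event = max(last_event, course_start if blank else onset)
            course_start = course_start + dt.timedelta(days=int(rng.integers(61, 120)))

        if rng.random() < 0.3:
            ra_id += 1
            rid = f"R{ra_id:05d}"
            r_date = dx_date + dt.timedelta(days=int(rng.integers(30, 150)))
            code = sorted(_RADIATION)[int(rng.integers(0, len(_RADIATION)))]
            rows["radiation"].append(
                {"radiation_id": rid, "patient_id": pid, "diagnosis_id": dx_id,
                 "radiation_start": r_date.isoformat(), "radiation_type": code}
            )
            ledger_map.append(
                {"person_id": pid, "source_table": "radiation", "source_row_id": rid,
                 "item": "Radiation type", "code": code,
                 "expected_concept_ids": ";".join(map(str, manual_expected[code]))}
            )
            last_event = max(last_event, r_date)

        n_followups = int(rng.integers(0, max(2, round(4 * config.report_intensity))))
        fu_base = max(last_event, dx_date + dt.timedelta(days=100))
        for k in range(n_followups):
            fu_id += 1
            fid = f"F{fu_id:05d}"
            f_date = fu_base + dt.timedelta(days=int(rng.integers(30, 120)) * (k + 1))
            code = sorted(_REMISSION)[int(rng.integers(0, len(_REMISSION)))]
            partial = rng.random() < 0.15
            if partial:
                f_date = f_date.replace(day=15)  # emitted as YYYY-MM, imputes back to the 15th
                date_str = f_date.isoformat()[:7]
            else:
                date_str = f_date.isoformat()
            rows["follow_up"].append(
                {"follow_up_id": fid, "patient_id": pid, "diagnosis_id": dx_id,
                 "assessment_date": date_str, "remission_status": code}
            )
            ledger_map.append(
                {"person_id": pid, "source_table": "follow_up", "source_row_id": fid,
                 "item": "Remission status", "code": code,
                 "expected_concept_ids": ";".join(map(str, expected("OBDS-FOLLOWUP", code)))}
            )
            last_event = max(last_event, f_date)

        if rng.random() < 0.15:
            d_date = last_event + dt.timedelta(days=int(rng.integers(30, 300)))
            rows["death"].append(
                {"patient_id": pid, "death_date": d_date.isoformat()}
            )

    tables = {}
    for name, recs in rows.items():
        schema_cols = {
            "patient": ["patient_id", "sex", "birth_year", "first_name", "last_name"],
            "diagnosis": ["diagnosis_id", "patient_id", "diagnosis_date", "icd10gm",
                          "icdo3_topography", "icdo3_morphology", "laterality",
                          "tnm_t", "tnm_n", "tnm_m", "tnm_date"],
            "surgery": ["surgery_id", "patient_id", "diagnosis_id", "surgery_date", "ops_code"],
            "systemic_therapy": ["therapy_id", "patient_id", "diagnosis_id",
                                 "therapy_start", "therapy_end"],
            "substance": ["substance_id", "therapy_id", "patient_id",
                          "substance_text", "administration_date"],
            "radiation": ["radiation_id", "patient_id", "diagnosis_id",
                          "radiation_start", "radiation_type"],
            "follow_up": ["follow_up_id", "patient_id", "diagnosis_id",
                          "assessment_date", "remission_status"],
            "side_effect": ["side_effect_id", "therapy_id", "patient_id",
                            "ctcae_code", "ctcae_grade", "onset_date"],
            "death": ["patient_id", "death_date"],
        }[name]
        frame = pd.DataFrame(recs, columns=schema_cols)
        frame.to_csv(directory / f"{name}.csv", index=False)
        tables[name] = frame

    ledger_mappings = pd.DataFrame(
        ledger_map,
        columns=["person_id", "source_table", "source_row_id", "item", "code",
                 "expected_concept_ids"],
    )
    ledger_regimens = pd.DataFrame(
        ledger_reg, columns=["person_id", "regimen_concept_id", "course_start"]
    )
    ledger_mappings.to_csv(directory / "ledger_mappings.csv", index=False)
    ledger_regimens.to_csv(directory / "ledger_regimens.csv", index=False)
    return RegistryBundle(
        directory=directory,
        tables=tables,
        ledger_mappings=ledger_mappings,
        ledger_regimens=ledger_regimens,
    )
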