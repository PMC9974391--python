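"""Bundled fixture data and the synthetic scale-up generator.

Two local health-information sources are emulated so every stage of the
engine runs self-contained, with no credentialed download:

* an intensive-care relational source (``mimic``) with the four tables the
  case studies touch — PATIENTS, ADMISSIONS, LABEVENTS, D_LABITEMS — holding
  the printed blood-gas glucose rows for subject 1 / admission 150809 and the
  admission-9 death-time discrepancy (patient table 0:00, admission table
  10:15);
* a flat-file diabetes source (``diabetes``) with two columns DATETIME, VALUE
  and its two printed glucose self-measurements.

``generate_synthetic_observations`` produces structurally identical sources
at configurable scale (seeded, deterministic) plus a manifest of expected
per-patient observation counts and death-time-conflict subjects, which the
test suite uses as its oracle.

Datetime conventions: lab chart times and the diabetes file use
DD/MM/YYYY HH:MM; the deidentified (future-shifted) death/admission columns
use MM/DD/YY H:MM with a 1970 pivot.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from . import fhir_schema, source_registry
from .graph_store import KnowledgeGraph
from .provenance import PrimaryDesignation
from .query_engine import CsvConnector, Engine, SqliteConnector
from .source_registry import (
    InternalJoin,
    LocalPropertyDef,
    MappingSpec,
    SourceDescriptor,
    TransformSpec,
)

MIMIC = "mimic"
DIABETES = "diabetes"
DIABETES_ENTITY = "DIABETES"
GLUCOSE_LOINC = "2339-0"
GLUCOSE_ITEMID = 50809

CHART_FMT = "%d/%m/%Y %H:%M"   # lab chart times & diabetes file
DEID_FMT = "%m/%d/%y %H:%M"    # deidentified death/admission dates

#: the four printed glucose lab events for subject 1 / admission 150809
TABLE4_LABEVENTS = [
    (1, 150809, GLUCOSE_ITEMID, "20/10/2018 20:04", "265", 265, "mg/dL", "abnormal"),
    (1, 150809, GLUCOSE_ITEMID, "20/10/2018 21:51", "267", 267, "mg/dL", "abnormal"),
    (1, 150809, GLUCOSE_ITEMID, "21/10/2018 00:42", "299", 299, "mg/dL", "abnormal"),
    (1, 150809, GLUCOSE_ITEMID, "21/10/2018 01:46", "294", 294, "mg/dL", "abnormal"),
]

#: the two printed diabetes self-measurements
TABLE5_DIABETES = [
    ("23/10/2018 08:00", "354"),
    ("23/10/2018 18:00", "275"),
]


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FHIR schema fixture


def build_fhir_schema_fixture() -> str:
    """Resource-definition JSON for Patient and Observation (byte-stable)."""
    doc = {
        "Patient": {
            "category": "fixture",
            "properties": {
                "id": {"type": "id", "description": "logical patient identifier"},
                "gender": {"type": "code"},
                "birthDate": {"type": "date"},
                "deceasedDateTime": {
                    "type": "dateTime",
                    "description": "date and time of death, when the patient is deceased",
                },
                "name": {
                    "type": "object",
                    "cardinality": "many",
                    "properties": {
                        "family": {"type": "string"},
                        "given": {"type": "string", "cardinality": "many"},
                    },
                },
            },
        },
        "Observation": {
            "category": "fixture",
            "properties": {
                "id": {"type": "id"},
                "status": {"type": "code"},
                "subject": {
                    "type": "object",
                    "properties": {
                        "reference": {"type": "Reference", "target": "Patient"},
                    },
                },
                "issued": {"type": "instant", "description": "when the result was issued"},
                "value": {"type": "decimal", "description": "observed value"},
                "Unit": {"type": "string", "description": "unit of measurement"},
                "coding": {
                    "type": "object",
                    "properties": {
                        "code": {"type": "code", "description": "observation type code (LOINC)"},
                        "system": {"type": "uri"},
                    },
                },
            },
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# local source fixtures

_MIMIC_TABLES: dict[str, list[tuple[str, str, str | None]]] = {
    # table -> [(column, value_type, datetime_format)]
    "PATIENTS": [
        ("SUBJECT_ID", "integer", None),
        ("GENDER", "string", None),
        ("DOB", "string", DEID_FMT),
        ("DOD", "string", DEID_FMT),
        ("DOD_HOSP", "string", DEID_FMT),
        ("DOD_SSN", "string", DEID_FMT),
        ("EXPIRE_FLAG", "integer", None),
    ],
    "ADMISSIONS": [
        ("SUBJECT_ID", "integer", None),
        ("HADM_ID", "integer", None),
        ("ADMITTIME", "string", DEID_FMT),
        ("DISCHTIME", "string", DEID_FMT),
        ("DEATHTIME", "string", DEID_FMT),
    ],
    "LABEVENTS": [
        ("SUBJECT_ID", "integer", None),
        ("HADM_ID", "integer", None),
        ("ITEMID", "integer", None),
        ("CHARTTIME", "string", CHART_FMT),
        ("VALUE", "string", None),
        ("VALUENUM", "float", None),
        ("VALUEUOM", "string", None),
        ("FLAG", "string", None),
    ],
    "D_LABITEMS": [
        ("ITEMID", "integer", None),
        ("LABEL", "string", None),
        ("FLUID", "string", None),
        ("CATEGORY", "string", None),
        ("LOINC_CODE", "string", None),
    ],
}

_SQL_TYPES = {"integer": "INTEGER", "float": "REAL", "string": "TEXT"}

FIXTURE_PATIENTS = [
    # SUBJECT_ID, GENDER, DOB, DOD, DOD_HOSP, DOD_SSN, EXPIRE_FLAG
    (1, "M", "03/06/85 00:00", None, None, None, 0),
    # the admission-9 patient: death recorded at 0:00 in the patient table,
    # 10:15 in the admission table; no social-security record
    (9, "F", "07/22/90 00:00", "11/14/49 00:00", "11/14/49 00:00", None, 1),
    # a patient whose hospital and social-security death dates disagree;
    # the date-of-death column follows the hospital record
    (17, "M", "01/30/77 00:00", "07/04/48 00:00", "07/04/48 00:00", "07/06/48 00:00", 1),
]

FIXTURE_ADMISSIONS = [
    # SUBJECT_ID, HADM_ID, ADMITTIME, DISCHTIME, DEATHTIME
    (1, 150809, "10/18/18 14:22", "10/23/18 11:00", None),
    (9, 9, "11/02/49 07:15", "11/14/49 10:15", "11/14/49 10:15"),
    (17, 17, "06/20/48 09:00", "07/04/48 08:30", "07/04/48 08:30"),
]

FIXTURE_D_LABITEMS = [
    (GLUCOSE_ITEMID, "Glucose", "Blood", "Blood gas", GLUCOSE_LOINC),
    (50971, "Potassium", "Blood", "Chemistry", "2823-3"),
]

FIXTURE_EXTRA_LABEVENTS = [
    # a potassium event for subject 1 and a glucose event for subject 9, so
    # the case-study query actually filters something
    (1, 150809, 50971, "20/10/2018 20:04", "4.1", 4.1, "mEq/L", None),
    (9, 9, GLUCOSE_ITEMID, "03/11/2049 06:30", "180", 180.0, "mg/dL", "abnormal"),
]


def _create_mimic_db(locator: str | Path) -> sqlite3.Connection:
    try:
        conn = sqlite3.connect(str(locator))
    except sqlite3.Error as exc:
        raise FixtureError(f"locator {locator!r} is not writable: {exc}") from exc
    for table, cols in _MIMIC_TABLES.items():
        conn.execute(f"DROP TABLE IF EXISTS {table}")
        decls = ", ".join(f"{name} {_SQL_TYPES[vtype]}" for name, vtype, _ in cols)
        conn.execute(f"CREATE TABLE {table} ({decls})")
    return conn


def build_mimic_fixture(locator: str | Path) -> str:
    """Write the relational intensive-care fixture database."""
    conn = _create_mimic_db(locator)
    with conn:
        conn.executemany("INSERT INTO PATIENTS VALUES (?,?,?,?,?,?,?)", FIXTURE_PATIENTS)
        conn.executemany("INSERT INTO ADMISSIONS VALUES (?,?,?,?,?)", FIXTURE_ADMISSIONS)
        conn.executemany("INSERT INTO D_LABITEMS VALUES (?,?,?,?,?)", FIXTURE_D_LABITEMS)
        conn.executemany(
            "INSERT INTO LABEVENTS VALUES (?,?,?,?,?,?,?,?)",
            TABLE4_LABEVENTS + FIXTURE_EXTRA_LABEVENTS,
        )
    conn.close()
    return str(locator)


def build_diabetes_fixture(locator: str | Path) -> str:
    """Write the two-column flat-file diabetes fixture."""
    path = Path(locator)
    try:
        with open(path, "w", newline="") as fh:
            fh.write("DATETIME,VALUE\n")
            for dt, value in TABLE5_DIABETES:
                fh.write(f"{dt},{value}\n")
    except OSError as exc:
        raise FixtureError(f"locator {locator!r} is not writable: {exc}") from exc
    return str(path)


# ---------------------------------------------------------------------------
# registry declarations for the two sources


def mimic_schema_listing() -> dict[str, list[LocalPropertyDef]]:
    return {
        table: [
            LocalPropertyDef(MIMIC, table, name, vtype, fmt)
            for name, vtype, fmt in cols
        ]
        for table, cols in _MIMIC_TABLES.items()
    }


def diabetes_schema_listing() -> list[LocalPropertyDef]:
    return [
        LocalPropertyDef(DIABETES, DIABETES_ENTITY, "DATETIME", "string", CHART_FMT),
        LocalPropertyDef(DIABETES, DIABETES_ENTITY, "VALUE", "integer", None),
    ]


def mimic_internal_joins() -> list[InternalJoin]:
    return [
        InternalJoin(MIMIC, ("LABEVENTS", "ITEMID"), ("D_LABITEMS", "ITEMID")),
        InternalJoin(MIMIC, ("LABEVENTS", "HADM_ID"), ("ADMISSIONS", "HADM_ID")),
        InternalJoin(MIMIC, ("ADMISSIONS", "SUBJECT_ID"), ("PATIENTS", "SUBJECT_ID")),
    ]


def standard_mappings(static_subject: int = 1) -> list[MappingSpec]:
    """The case-study mapping declarations for both sources."""
    glucose_ctx = (("Observation.coding.code", GLUCOSE_LOINC),)
    return [
        # intensive-care source: lab events joined to the lab-item dictionary
        MappingSpec("Observation.subject.reference", "DIRECT", (MIMIC, "LABEVENTS", "SUBJECT_ID")),
        MappingSpec("Observation.issued", "DIRECT", (MIMIC, "LABEVENTS", "CHARTTIME")),
        MappingSpec("Observation.value", "DIRECT", (MIMIC, "LABEVENTS", "VALUENUM")),
        MappingSpec("Observation.Unit", "DIRECT", (MIMIC, "LABEVENTS", "VALUEUOM")),
        MappingSpec("Observation.coding.code", "DIRECT", (MIMIC, "D_LABITEMS", "LOINC_CODE")),
        MappingSpec("Patient.id", "DIRECT", (MIMIC, "PATIENTS", "SUBJECT_ID")),
        MappingSpec("Patient.id", "DIRECT", (MIMIC, "ADMISSIONS", "SUBJECT_ID")),
        MappingSpec("Patient.gender", "DIRECT", (MIMIC, "PATIENTS", "GENDER")),
        MappingSpec("Patient.deceasedDateTime", "DIRECT", (MIMIC, "PATIENTS", "DOD_HOSP")),
        MappingSpec("Patient.deceasedDateTime", "DIRECT", (MIMIC, "PATIENTS", "DOD_SSN")),
        MappingSpec("Patient.deceasedDateTime", "DIRECT", (MIMIC, "ADMISSIONS", "DEATHTIME")),
        # diabetes flat file: contextual (glucose only), sparse columns plus
        # STATIC semantic annotations
        MappingSpec("Observation.issued", "DIRECT", (DIABETES, DIABETES_ENTITY, "DATETIME"),
                    context=glucose_ctx),
        MappingSpec("Observation.value", "DIRECT", (DIABETES, DIABETES_ENTITY, "VALUE"),
                    context=glucose_ctx),
        MappingSpec("Observation.subject.reference", "STATIC", static_value=static_subject,
                    source_id=DIABETES, context=glucose_ctx),
        MappingSpec("Observation.coding.code", "STATIC", static_value=GLUCOSE_LOINC,
                    source_id=DIABETES, context=glucose_ctx),
        MappingSpec("Observation.Unit", "STATIC", static_value="mg/dL",
                    source_id=DIABETES, context=glucose_ctx),
    ]


DECEASED_DESIGNATION = PrimaryDesignation(
    fhir_path="Patient.deceasedDateTime",
    source_id=MIMIC,
    tie_break_order=(
        f"{MIMIC}.PATIENTS.DOD_HOSP",
        f"{MIMIC}.PATIENTS.DOD_SSN",
        f"{MIMIC}.ADMISSIONS.DEATHTIME",
    ),
)


def build_registry(
    graph: KnowledgeGraph,
    mimic_locator: str,
    diabetes_locator: str,
    mappings: list[MappingSpec] | None = None,
) -> None:
    """Register both sources, their schemas, joins and mappings into ``graph``."""
    source_registry.register_source(
        SourceDescriptor(MIMIC, "relational", str(mimic_locator)), graph
    )
    source_registry.register_source(
        SourceDescriptor(DIABETES, "flat_file", str(diabetes_locator)), graph
    )
    source_registry.import_relational_schema(MIMIC, mimic_schema_listing(), graph)
    source_registry.declare_flat_schema(DIABETES, diabetes_schema_listing(), graph)
    for join in mimic_internal_joins():
        source_registry.add_internal_join(join, graph)
    source_registry.add_transform(
        TransformSpec("mmol_to_mgdl", "linear_unit", {"factor": 18.0, "offset": 0.0}), graph
    )
    source_registry.add_transform(
        TransformSpec(
            "deid_to_chart",
            "datetime_reformat",
            {"source_format": DEID_FMT, "target_format": CHART_FMT},
        ),
        graph,
    )
    for spec in mappings if mappings is not None else standard_mappings():
        source_registry.add_mapping(spec, graph)


def build_demo_engine(workdir: str | Path) -> Engine:
    """Build the full case-study engine (schema, sources, registry) in one go."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    schema_path = workdir / "fhir_schema.json"
    schema_path.write_text(build_fhir_schema_fixture())
    mimic_path = build_mimic_fixture(workdir / "mimic.db")
    diabetes_path = build_diabetes_fixture(workdir / "diabetes.csv")
    (workdir / "mappings.csv").write_text(
        source_registry.dump_mapping_csv(standard_mappings())
    )
    graph = KnowledgeGraph()
    defs = fhir_schema.parse_resource_definitions(schema_path.read_text())
    fhir_schema.build_knowledge_graph(defs, graph)
    build_registry(graph, mimic_path, diabetes_path)
    return Engine(
        graph=graph,
        connectors={
            MIMIC: SqliteConnector(mimic_path),
            DIABETES: CsvConnector(diabetes_path),
        },
        subject_key_paths={"Observation": "subject.reference", "Patient": "id"},
        designations={DECEASED_DESIGNATION.fhir_path: DECEASED_DESIGNATION},
    )


# ---------------------------------------------------------------------------
# synthetic scale-up


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_patients: int = 50
    n_observations_per_patient: int = 4
    glucose_mean: float = 180.0  # mg/dL, a diabetic-range level
    glucose_sd: float = 45.0
    conflict_rate: float = 0.2  # fraction of patients given inconsistent death times
    datetime_span: tuple[str, str] = ("2018-10-01", "2018-12-31")  # ISO dates

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_observations_per_patient < 0:
            raise FixtureError("counts must be non-negative")
        if self.glucose_sd < 0:
            raise FixtureError("glucose_sd must be non-negative")
        if not 0 <= self.conflict_rate <= 1:
            raise FixtureError("conflict_rate must be within [0, 1]")


def _random_charttime(rng: np.random.Generator, start: datetime, end: datetime) -> str:
    minutes = int((end - start).total_seconds() // 60)
    return (start + timedelta(minutes=int(rng.integers(0, max(minutes, 1))))).strftime(CHART_FMT)


def _truncated_glucose(rng: np.random.Generator, mean: float, sd: float) -> int:
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > 0:
            return int(round(value))
    return max(int(round(mean)), 1)


def generate_synthetic_observations(config: FixtureConfig, outdir: str | Path) -> dict:
    """Generate scaled-up versions of both sources plus an expectation manifest.

    Every patient gets one admission and ``n_observations_per_patient``
    glucose lab events; patient 1 additionally owns the flat-file source's
    rows.  A ``conflict_rate`` fraction of patients (the highest subject ids)
    are deceased with a death time that disagrees between the patient and
    admission tables; an equal-sized preceding block is deceased with
    agreeing records.  Same seed, same files, byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    start = datetime.fromisoformat(config.datetime_span[0])
    end = datetime.fromisoformat(config.datetime_span[1])
    if end <= start:
        raise FixtureError("datetime_span end must be after start")

    n = config.n_patients
    n_conflict = int(round(config.conflict_rate * n))
    conflict_subjects = list(range(n - n_conflict + 1, n + 1))
    n_consistent = min(n_conflict, n - n_conflict)
    consistent_deceased = list(range(n - n_conflict - n_consistent + 1, n - n_conflict + 1))

    patients, admissions, labevents = [], [], []
    for sid in range(1, n + 1):
        gender = "F" if rng.integers(0, 2) else "M"
        dod = dod_hosp = deathtime = None
        if sid in conflict_subjects or sid in consistent_deceased:
            day = start + timedelta(days=int(rng.integers(0, (end - start).days or 1)))
            dod = dod_hosp = day.strftime("%m/%d/%y") + " 00:00"
            deathtime = day.strftime("%m/%d/%y") + (
                " 10:15" if sid in conflict_subjects else " 00:00"
            )
        patients.append((sid, gender, "01/01/70 00:00", dod, dod_hosp, None, int(dod is not None)))
        hadm = 150000 + sid
        admit = start.strftime("%m/%d/%y %H:%M")
        admissions.append((sid, hadm, admit, deathtime or end.strftime("%m/%d/%y %H:%M"), deathtime))
        for _ in range(config.n_observations_per_patient):
            value = _truncated_glucose(rng, config.glucose_mean, config.glucose_sd)
            labevents.append(
                (sid, hadm, GLUCOSE_ITEMID, _random_charttime(rng, start, end),
                 str(value), float(value), "mg/dL", None)
            )

    mimic_path = outdir / "mimic.db"
    conn = _create_mimic_db(mimic_path)
    with conn:
        conn.executemany("INSERT INTO PATIENTS VALUES (?,?,?,?,?,?,?)", patients)
        conn.executemany("INSERT INTO ADMISSIONS VALUES (?,?,?,?,?)", admissions)
        conn.executemany("INSERT INTO D_LABITEMS VALUES (?,?,?,?,?)", FIXTURE_D_LABITEMS)
        conn.executemany("INSERT INTO LABEVENTS VALUES (?,?,?,?,?,?,?,?)", labevents)
    conn.close()

    diabetes_rows = config.n_observations_per_patient if n >= 1 else 0
    diabetes_path = outdir / "diabetes.csv"
    with open(diabetes_path, "w", newline="") as fh:
        fh.write("DATETIME,VALUE\n")
        for _ in range(diabetes_rows):
            value = _truncated_glucose(rng, config.glucose_mean, config.glucose_sd)
            fh.write(f"{_random_charttime(rng, start, end)},{value}\n")

    manifest = {
        "seed": config.seed,
        "n_patients": n,
        "glucose_mean": config.glucose_mean,
        "glucose_sd": config.glucose_sd,
        "per_patient_mimic": {str(sid): config.n_observations_per_patient for sid in range(1, n + 1)},
        "diabetes_rows": diabetes_rows,
        "expected_query_counts": {
            str(sid): config.n_observations_per_patient + (diabetes_rows if sid == 1 else 0)
            for sid in range(1, n + 1)
        },
        "conflict_subjects": conflict_subjects,
        "consistent_deceased_subjects": consistent_deceased,
        "mimic_locator": str(mimic_path),
        "diabetes_locator": str(diabetes_path),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def build_synthetic_engine(config: FixtureConfig, workdir: str | Path) -> tuple[Engine, dict]:
    """Generate synthetic sources and assemble an engine over them."""
    workdir = Path(workdir)
    manifest = generate_synthetic_observations(config, workdir)
    graph = KnowledgeGraph()
    defs = fhir_schema.parse_resource_definitions(build_fhir_schema_fixture())
    fhir_schema.build_knowledge_graph(defs, graph)
    build_registry(graph, manifest["mimic_locator"], manifest["diabetes_locator"])
    engine = Engine(
        graph=graph,
        connectors={
            MIMIC: SqliteConnector(manifest["mimic_locator"]),
            DIABETES: CsvConnector(manifest["diabetes_locator"]),
        },
        subject_key_paths={"Observation": "subject.reference", "Patient": "id"},
        designations={DECEASED_DESIGNATION.fhir_path: DECEASED_DESIGNATION},
    )
    return engine, manifest
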