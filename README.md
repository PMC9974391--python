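# fhirkg

An FHIR-centric knowledge graph with **ostensive provenance** and **federated
query** over heterogeneous clinical data sources.

## The problem

HL7 FHIR defines health-data concepts *lexically*: a resource such as
`Patient` or `Observation` carries named attributes with prose definitions.
When several local systems (a hospital data warehouse, a patient's flat-file
glucose log) each map their own columns onto those attributes, the same FHIR
path can end up meaning subtly different things — three different "death
time" columns, two disagreeing timestamps, mixed units. `fhirkg` complements
the lexical definition with an *ostensive* one: for any FHIR attribute it can
show exactly which sources, tables and columns back it, fetch the concrete
stored values for a patient as examples, flag the places where sources
disagree, and still answer FHIR-phrased queries federated across all of them.

It is aimed at health-informatics engineers integrating relational and
flat-file clinical sources behind a single FHIR-shaped query surface.

## The model

Everything lives in one property graph `G = (N, E)` with four node labels:

* **Source** — a registered data source (connection info, kind:
  relational or flat file);
* **Entity** — an FHIR resource, a database table, or a flat file's
  logical record;
* **Property** — an FHIR attribute (dotted path such as
  `Observation.coding.code`) or a local column;
* **Mapping** — the relation between a local property and an FHIR path.

A mapping is `DIRECT` (column ↔ path), `STATIC` (a constant semantic
annotation injected into sparse sources, e.g. a fixed patient reference and
LOINC code for a single-patient glucose file), or `TRANSFORM` (column ↔ path
through a declared function such as a linear unit conversion
`y = a·x + b` or a datetime reformat). A mapping may carry a *context
predicate* — a conjunction of `path = literal` equalities — restricting when
it applies (the glucose file answers only queries for LOINC `2339-0`).
Intra-source `JOINS` edges declare key relationships between tables.

A federated query runs in ten steps: parse the FHIR-phrased query → discover
context-satisfied mappings → plan a minimal join tree per source → render
ANSI SQL (or a flat-file scan) → execute → annotate statics → re-map columns
to FHIR paths (dropping unmapped ones, applying transforms) → link patient
records across sources → row-append into a unified data mart with per-row
provenance → emit FHIR JSON resource instances.

## Worked example

The bundled fixtures emulate two local sources: an intensive-care relational
database (tables `PATIENTS`, `ADMISSIONS`, `LABEVENTS`, `D_LABITEMS`) and a
two-column flat-file diabetes log. A blood-glucose query for patient 1:

```python
from fhirkg import build_demo_engine, parse_fhir_query, run_federated_query

engine = build_demo_engine("work")
query = parse_fhir_query(
    "SELECT subject.reference, issued, value, Unit, coding.code "
    "FROM Observation WHERE coding.code = '2339-0' AND subject.reference = 1",
    engine.graph,
)
result = run_federated_query(engine, query)
print(result.mart.to_csv(include_provenance=True))
```

prints the unified six-row mart (four hospital lab events + two
self-measurements, every value in mg/dL under LOINC 2339-0):

```
FHIR.Observation.subject.reference,FHIR.Observation.issued,FHIR.Observation.value,FHIR.Observation.Unit,FHIR.Observation.coding.code,_source
1,20/10/2018 20:04,265,mg/dL,2339-0,mimic
1,20/10/2018 21:51,267,mg/dL,2339-0,mimic
1,21/10/2018 00:42,299,mg/dL,2339-0,mimic
1,21/10/2018 01:46,294,mg/dL,2339-0,mimic
1,23/10/2018 08:00,354,mg/dL,2339-0,diabetes
1,23/10/2018 18:00,275,mg/dL,2339-0,diabetes
```

The ostensive side — who backs `Patient.deceasedDateTime`, and do they
agree for the patient of admission 9?

```python
from fhirkg import reverse_lookup, trace_value, detect_value_conflicts

for r in reverse_lookup("Patient.deceasedDateTime", engine.graph):
    print(r.source_id, r.entity_name, r.property_name)
# mimic ADMISSIONS DEATHTIME
# mimic PATIENTS DOD_HOSP
# mimic PATIENTS DOD_SSN

alerts = detect_value_conflicts("Patient.deceasedDateTime", 9, engine)
# one value_mismatch alert: the patient table says 11/14/49 00:00,
# the admission table 11/14/49 10:15
```

With the hospital column designated primary, `resolve_primary` returns the
hospital record and lists the discarded alternatives.

The same is available from a shell:

```sh
fhirkg fixtures build --out work
fhirkg query --workdir work --resource Observation \
       --where coding.code=2339-0 --where subject.reference=1
fhirkg trace --workdir work --path Patient.deceasedDateTime --subject 9
fhirkg validate --workdir work
```

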