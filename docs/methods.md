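# Methods

## The graph substrate

The knowledge graph is an in-process property graph (backed by a
`networkx.MultiDiGraph`) rather than a graph-database server: every
operation the engine needs — attribute-equality search, typed-relation
traversal, 1-hop topology — is closed-form over a desk-scale graph, and an
in-process store makes the whole system testable without infrastructure. A
Cypher-dialect text export (`export_script`) and a line-delimited JSON dump
are provided; both round-trip to a content-identical graph, and the Cypher
property maps are emitted with quoted keys so they parse as plain JSON and
survive values containing colons (timestamps).

Node identity is a stable SHA-1 prefix of `(label, qualified name)` for
every declaratively created node (`FHIR.Patient.deceasedDateTime`,
`local.mimic.LABEVENTS.ITEMID`, `mapping.<content-hash>`), so rebuilding the
same registry — in any declaration order — produces a byte-identical dump.
All query results are sorted (nodes by id, result rows by value) because
no ordering is otherwise defined; determinism is a design requirement, not
an optimisation.

Attribute values are restricted to scalars; anything nested is expressed
with additional nodes and edges, exactly as FHIR sub-objects become their
own Property nodes.

## FHIR schema dialect

Resource definitions are read from a simplified FHIR-like JSON dialect
(resource → properties → nested sub-objects). Official FHIR
StructureDefinitions are deliberately out of scope: the parser's contract
is written against the bundled dialect, which carries exactly the structure
the engine consumes (names, value types, cardinality, reference targets,
nesting). Nested objects flatten to dotted paths without a depth limit; an
intermediate object is itself a property node (so `subject` and
`subject.reference` both resolve). Path matching is case-sensitive, as FHIR
attribute names are in practice. Which FHIR version's resource list to load
is a user concern; the fixture pins none.

## Mappings, context, transforms

A `MappingSpec` is identified by a content hash, making re-registration
idempotent. The three kinds partition cleanly: `DIRECT`/`TRANSFORM` carry a
local `(source, entity, property)` reference and no constant; `STATIC`
carries a constant and no reference. Context predicates are conjunctions of
`(FHIR path = literal)` equalities — the only form the case material
motivates; a context is satisfied only when the query actually filters on
the context path with the matching literal, so a contextual source is
excluded both when the query asks for a different code and when it asks for
none.

The transform vocabulary is `linear_unit` (`y = a·x + b`, `a ≠ 0`, hence
always invertible; the bundled `mmol_to_mgdl` uses the conventional glucose
factor 18.0) and `datetime_reformat` (explicit strptime/strftime pattern
pair, invertible by swapping the patterns). Nothing richer is implemented
because no richer function is needed by any declared mapping.

## Query planning

Filters are equality-only. Per source, the planner binds each selected path
to a mapping (STATIC bindings become constants, not selections), translates
each filter through the source's mapping (a STATIC mapping satisfies a
filter iff its constant equals the literal, otherwise the source is
excluded), and connects the required entities with a minimal join tree:
shortest paths over the declared `JOINS` edges from the anchor entity (the
one carrying the most selections), unioned. Entities reachable only through
the join tree are added; entities that nothing selects or filters are not —
the returned columns are exactly those of the entities the query actually
needs. Rendered SQL is deterministic: all columns of the plan's entities in
declaration order (first occurrence wins on name collisions across joined
tables), equi-join conditions in tree order, an ORDER BY over every output
column. Flat-file sources render a scan specification (projection +
conjunctive row predicate) executed by the CSV connector.

Filter literals are cast through the local column's declared value type
before rendering, so an integer key column is compared as an integer.

## Integration

Re-mapped tables name their columns `FHIR.<path>`; the unified mart's
canonical column order is `subject.reference, issued, value, Unit,
coding.code`, then any further paths lexically. The numeric lab column
(`VALUENUM`) is the one mapped to `Observation.value` — the text duplicate
`VALUE` is disregarded, since the FHIR value must be numeric. Record
linkage is deterministic: an explicit identifier-equivalence map assigns
canonical keys; no rows are dropped or merged. Row-append conserves row
count exactly, fills columns absent from a source with explicit nulls
(empty CSV cells, omitted JSON keys), and orders rows by issued timestamp
then source id. Emission nests dotted paths into JSON objects;
`flatten_resource` is its exact inverse, and the pair is a bijection on any
mart without nesting conflicts.

## Datetimes

Every local datetime column declares its format pattern at registration.
Two conventions appear in the bundled data: lab chart times and the
flat-file log use `DD/MM/YYYY HH:MM`; the deidentified (future-shifted)
death and admission columns use `MM/DD/YY H:MM`, resolved with a fixed
pivot of 1970 (window 1970–2069). FHIR-shaped tables keep the
`DD/MM/YYYY HH:MM` display rendering; all comparison — row ordering,
conflict detection — happens on ISO-8601 renderings at minute precision,
so 00:00 versus 10:15 on one calendar day is a genuine mismatch while
format differences alone are not.

## Provenance and conflict policy

Conflicts are reported, never silently resolved: `detect_value_conflicts`
emits one alert per pair of backing locations with differing normalised
values, and registry validation alerts when a path is backed by two or more
local references without a primary designation. Resolution happens only
under an explicit `PrimaryDesignation`, whose `tie_break_order` is a list
of `source.entity.property` references (first non-null wins) — reference-
level rather than source-level, because the motivating rule (the hospital
death column outranks the social-security one) discriminates between
columns of a single table.

## Fixtures and the synthetic generator

The bundled fixtures embed, verbatim, the case-study rows: four glucose lab
events for subject 1 / admission 150809 (values 265, 267, 299, 294 mg/dL,
LOINC 2339-0), two flat-file self-measurements (354, 275 mg/dL), and the
admission-9 death-time discrepancy (patient table 00:00, admission table
10:15; the social-security column is null for that patient, while a second
deceased patient carries disagreeing hospital/social-security dates). The
glucose item id 50809 is a realistic blood-gas glucose dictionary entry.
Full-scale clinical datasets (tens of thousands of admissions, hundreds of
thousands of log records) are credentialed or external and are not
reproduced; the generator stands in for scale.

`generate_synthetic_observations` emulates the same two-source structure at
configurable size: per patient one admission and a fixed number of glucose
events, values drawn from a normal distribution truncated at zero
(default mean 180 mg/dL, sd 45 — a plausible diabetic profile), chart times
uniform over the configured span (default autumn 2018). A `conflict_rate`
fraction of patients (default 0.2) are deceased with planted
patient-vs-admission death-time disagreements, and an equal-sized block is
deceased with agreeing records, so conflict detection has both positives
and negatives. The flat-file source remains single-patient (patient 1),
matching its STATIC subject annotation. A manifest records expected
per-patient federated query counts and the planted conflict subjects; the
tests and the acceptance script treat it as the oracle. Everything is
driven by one seed; the same seed reproduces the same files.

What the generator does *not* emulate: missing or malformed values, irregular
per-patient event counts, multiple admissions per patient, multiple lab
items per source, or realistic inter-source timestamp jitter. Passing the
manifest oracle therefore shows the pipeline's accounting is exact under
clean inputs; it does not certify behaviour on dirty real-world extracts
beyond the explicit error paths the unit tests exercise.

## Problem sizes

The default test run uses desk-scale inputs throughout: random graphs of a
few hundred nodes for the store oracles, 50 random two/three-table
databases for the SQL-vs-nested-loop check, and synthetic cohorts of 50
patients (three seeds) for the manifest oracle — sizes chosen so the whole
suite and the acceptance script each complete in seconds while still
exercising every code path at non-trivial cardinality.

## Known limitations

* Only equality filters; no ranges, no negation (the case material uses
  nothing else).
* Schema matching is declarative; no automatic/learned matching, no
  terminology services (LOINC codes are opaque literals).
* Record linkage is deterministic via the equivalence map; probabilistic
  linkage is out of scope.
* The relational dialect is the embedded database's ANSI subset; no query
  optimisation beyond the minimal join tree; read-only.
* No server surface, transactions, or concurrent mutation contract.
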