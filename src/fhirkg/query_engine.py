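"""Federated query engine: FHIR-phrased queries over heterogeneous sources.

A query is phrased purely in FHIR terms (resource type, selected paths,
equality filters).  The engine discovers which registered sources can satisfy
it through their mapping nodes (honouring contextual mappings), plans the
intra-source joins needed, renders a per-source query — ANSI SQL for
relational sources, a scan specification for flat files — executes it, and
hands the per-source results to the integrator for annotation, re-mapping
and row-append integration.

The flow of :func:`run_federated_query` is: parse → discover → plan →
render → execute → annotate → remap → transform → integrate → emit, with
per-source provenance kept on every output row.
"""

from __future__ import annotations

import csv
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from . import fhir_schema, source_registry
from .graph_store import KnowledgeGraph
from .source_registry import InternalJoin, MappingSpec, mapping_spec_of


class QueryError(ValueError):
    pass


class SourceExcluded(Exception):
    """Raised during planning when a source cannot satisfy the query
    (contradicted STATIC binding or an unmappable filter); the source then
    simply contributes no plan."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# query representation


@dataclass(frozen=True)
class FhirQuery:
    resource_type: str
    select: tuple[str, ...]  # dotted paths relative to the resource
    filters: tuple[tuple[str, str, object], ...] = ()  # (relative path, "=", literal)

    def full_path(self, relative: str) -> str:
        return f"{self.resource_type}.{relative}"

    def filter_literal(self, full_path: str) -> object | None:
        for path, _, literal in self.filters:
            if self.full_path(path) == full_path:
                return literal
        return None


_SQL_QUERY_RE = re.compile(
    r"^\s*SELECT\s+(?P<select>.+?)\s+FROM\s+(?P<resource>\w+)"
    r"(?:\s+WHERE\s+(?P<where>.+?))?\s*;?\s*$",
    re.IGNORECASE | re.DOTALL,
)


def _parse_literal(text: str) -> object:
    text = text.strip()
    if len(text) >= 2 and text[0] == text[-1] and text[0] in "'\"":
        return text[1:-1]
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def parse_fhir_query(spec: str | Mapping, graph: KnowledgeGraph | None = None) -> FhirQuery:
    """Build a FhirQuery from a mapping or an SQL-like surface syntax.

    The surface form is ``SELECT <paths> FROM <Resource> WHERE <path>=<lit>
    AND ...``; paths are dotted and relative to the resource.  When a graph
    is supplied every path is resolved against it and an unresolvable path
    is rejected by name.
    """
    if isinstance(spec, Mapping):
        query = FhirQuery(
            resource_type=spec["resource_type"],
            select=tuple(spec["select"]),
            filters=tuple((f[0], "=", f[-1]) for f in spec.get("filters", ())),
        )
    else:
        m = _SQL_QUERY_RE.match(spec)
        if not m:
            raise QueryError(f"unparseable query: {spec!r}")
        select = tuple(p.strip() for p in m.group("select").split(","))
        filters = []
        if m.group("where"):
            for clause in re.split(r"\s+AND\s+", m.group("where"), flags=re.IGNORECASE):
                if "=" not in clause:
                    raise QueryError(f"only equality filters are supported: {clause!r}")
                path, literal = clause.split("=", 1)
                filters.append((path.strip(), "=", _parse_literal(literal)))
        query = FhirQuery(m.group("resource"), select, tuple(filters))
    if not query.select:
        raise QueryError("query must select at least one path")
    if graph is not None:
        for rel in list(query.select) + [f[0] for f in query.filters]:
            fhir_schema.resolve_path(graph, query.full_path(rel))
    return query


def render_fhir_query(query: FhirQuery) -> str:
    """Inverse of the SQL-like surface syntax; parse(render(q)) == q."""
    text = f"SELECT {', '.join(query.select)} FROM {query.resource_type}"
    if query.filters:
        clauses = []
        for path, _, literal in query.filters:
            rendered = f"'{literal}'" if isinstance(literal, str) else repr(literal)
            clauses.append(f"{path} = {rendered}")
        text += " WHERE " + " AND ".join(clauses)
    return text


# ---------------------------------------------------------------------------
# mapping discovery


@dataclass(frozen=True)
class MappingHit:
    mapping: MappingSpec
    source_id: str
    entity_name: str | None  # None for STATIC
    property_name: str | None
    fhir_path: str


def _context_satisfied(spec: MappingSpec, query: FhirQuery) -> bool:
    for ctx_path, ctx_literal in spec.context:
        literal = query.filter_literal(ctx_path)
        if literal is None or str(literal) != str(ctx_literal):
            return False
    return True


def discover_mappings(query: FhirQuery, graph: KnowledgeGraph) -> list[MappingHit]:
    """All context-satisfied mapping hits for the query's select and filter paths.

    A select path with zero hits in every source is an error (the query is
    unanswerable); filter paths may go unmapped per source — planning then
    excludes that source.
    """
    needed = [query.full_path(p) for p in query.select]
    filter_paths = [query.full_path(f[0]) for f in query.filters]
    hits: list[MappingHit] = []
    for path in dict.fromkeys(needed + filter_paths):
        fhir_schema.resolve_path(graph, path)
        for node in graph.find_nodes("Mapping", {"fhir_path": path}):
            spec = mapping_spec_of(node)
            if not _context_satisfied(spec, query):
                continue
            hits.append(
                MappingHit(
                    mapping=spec,
                    source_id=spec.source_id,
                    entity_name=spec.local_ref[1] if spec.local_ref else None,
                    property_name=spec.local_ref[2] if spec.local_ref else None,
                    fhir_path=path,
                )
            )
    covered = {h.fhir_path for h in hits}
    uncovered = [p for p in needed if p not in covered]
    if uncovered:
        raise QueryError(f"no mapping in any source covers: {', '.join(uncovered)}")
    hits.sort(key=lambda h: (h.source_id, h.fhir_path, h.entity_name or "", h.property_name or ""))
    return hits


def hits_by_source(hits: Sequence[MappingHit]) -> dict[str, list[MappingHit]]:
    grouped: dict[str, list[MappingHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.source_id, []).append(hit)
    return dict(sorted(grouped.items()))


# ---------------------------------------------------------------------------
# planning


@dataclass
class QueryPlan:
    source_id: str
    source_kind: str
    entities: list[str]  # anchor first, then join-tree breadth-first order
    join_conditions: list[InternalJoin]
    selections: list[tuple[str, str, str]]  # (entity, property, fhir_path)
    filter_conditions: list[tuple[str, str, object]]  # (entity, property, literal)
    static_bindings: list[tuple[str, object]]  # (fhir_path, literal)
    output_columns: list[tuple[str, str]] = field(default_factory=list)  # (entity, column)


def _typed_literal(graph: KnowledgeGraph, source_id: str, entity: str, prop: str, literal: object) -> object:
    node = source_registry.local_property_node(graph, source_id, entity, prop)
    vtype = node.get("value_type", "string")
    try:
        if vtype in {"integer", "int"}:
            return int(literal)
        if vtype in {"float", "decimal", "real", "numeric"}:
            return float(literal)
    except (TypeError, ValueError) as exc:
        raise QueryError(
            f"filter literal {literal!r} cannot be cast to {vtype} for {entity}.{prop}"
        ) from exc
    return str(literal)


def plan_source_query(
    source_hits: Sequence[MappingHit], graph: KnowledgeGraph, query: FhirQuery
) -> QueryPlan:
    """Translate one source's mapping hits into an executable plan.

    Raises :class:`SourceExcluded` when a STATIC binding contradicts a query
    filter or a filter path has no mapping in this source; raises
    :class:`QueryError` when required entities cannot be connected through
    declared joins.
    """
    if not source_hits:
        raise QueryError("cannot plan with no hits")
    source_id = source_hits[0].source_id
    src = source_registry._source_node(graph, source_id)

    by_path: dict[str, list[MappingHit]] = {}
    for hit in source_hits:
        by_path.setdefault(hit.fhir_path, []).append(hit)

    selections: list[tuple[str, str, str]] = []
    static_bindings: list[tuple[str, object]] = []
    for rel in query.select:
        path = query.full_path(rel)
        candidates = sorted(
            by_path.get(path, ()),
            key=lambda h: (h.entity_name or "", h.property_name or ""),
        )
        if not candidates:
            raise SourceExcluded(f"{source_id} does not map {path}")
        hit = candidates[0]
        if hit.mapping.kind == "STATIC":
            static_bindings.append((path, hit.mapping.static_value))
        else:
            selections.append((hit.entity_name, hit.property_name, path))

    filter_conditions: list[tuple[str, str, object]] = []
    for rel, _, literal in query.filters:
        path = query.full_path(rel)
        candidates = sorted(
            by_path.get(path, ()),
            key=lambda h: (h.entity_name or "", h.property_name or ""),
        )
        if not candidates:
            raise SourceExcluded(f"{source_id} cannot express filter on {path}")
        hit = candidates[0]
        if hit.mapping.kind == "STATIC":
            if str(hit.mapping.static_value) != str(literal):
                raise SourceExcluded(
                    f"{source_id}: static {path}={hit.mapping.static_value!r} "
                    f"contradicts filter literal {literal!r}"
                )
        else:
            typed = _typed_literal(graph, source_id, hit.entity_name, hit.property_name, literal)
            filter_conditions.append((hit.entity_name, hit.property_name, typed))

    required = list(dict.fromkeys(
        [e for e, _, _ in selections] + [e for e, _, _ in filter_conditions]
    ))
    if not required:
        raise SourceExcluded(f"{source_id} satisfies the query with statics only (no data rows)")

    # anchor: entity carrying the most selections, ties broken lexically
    weight = {e: sum(1 for s in selections if s[0] == e) for e in required}
    anchor = max(sorted(required), key=lambda e: weight[e])

    joins = source_registry.iter_joins(graph, source_id)
    jg = nx.Graph()
    jg.add_nodes_from(required)
    join_lookup: dict[tuple[str, str], InternalJoin] = {}
    for join in joins:
        a, b = join.left[0], join.right[0]
        jg.add_edge(a, b)
        join_lookup[(a, b)] = join
        join_lookup[(b, a)] = join

    entities = [anchor]
    join_conditions: list[InternalJoin] = []
    for target in sorted(required):
        if target == anchor:
            continue
        try:
            path_nodes = nx.shortest_path(jg, anchor, target)
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            raise QueryError(
                f"{source_id}: entities {anchor!r} and {target!r} are not connected by declared joins"
            )
        for a, b in zip(path_nodes, path_nodes[1:]):
            if b not in entities:
                entities.append(b)
                join_conditions.append(join_lookup[(a, b)])

    # output: every column of every plan entity, deduplicated by name
    output_columns: list[tuple[str, str]] = []
    seen: set[str] = set()
    for entity in entities:
        for col in source_registry.entity_columns(graph, source_id, entity):
            if col["name"] not in seen:
                seen.add(col["name"])
                output_columns.append((entity, col["name"]))

    return QueryPlan(
        source_id=source_id,
        source_kind=src["kind"],
        entities=entities,
        join_conditions=join_conditions,
        selections=selections,
        filter_conditions=filter_conditions,
        static_bindings=sorted(static_bindings),
        output_columns=output_columns,
    )


# ---------------------------------------------------------------------------
# rendering


def _sql_literal(value: object) -> str:
    if isinstance(value, str):
        return "'" + value.replace("'", "''") + "'"
    return str(value)


def render_relational_query(plan: QueryPlan) -> str:
    """ANSI SELECT over the plan's join tree (or a scan-spec for flat files)."""
    if plan.source_kind == "flat_file":
        entity = plan.entities[0]
        cols = ", ".join(c for _, c in plan.output_columns)
        text = f"SCAN {plan.source_id}.{entity} SELECT {cols}"
        if plan.filter_conditions:
            preds = " AND ".join(
                f"{prop} = {_sql_literal(lit)}" for _, prop, lit in plan.filter_conditions
            )
            text += f" WHERE {preds}"
        return text + ";"
    select = ", ".join(f"{e}.{c} AS {c}" for e, c in plan.output_columns)
    text = f"SELECT {select}\nFROM {plan.entities[0]}"
    joined = {plan.entities[0]}
    for join in plan.join_conditions:
        (le, lp), (re_, rp) = join.left, join.right
        new = re_ if le in joined else le
        text += f"\nJOIN {new} ON {le}.{lp} = {re_}.{rp}"
        joined.add(new)
    if plan.filter_conditions:
        preds = " AND ".join(
            f"{e}.{p} = {_sql_literal(lit)}" for e, p, lit in plan.filter_conditions
        )
        text += f"\nWHERE {preds}"
    order = ", ".join(c for _, c in plan.output_columns)
    text += f"\nORDER BY {order};"
    return text


# ---------------------------------------------------------------------------
# connectors & execution


@dataclass
class ResultTable:
    source_id: str
    columns: list[str]
    rows: list[tuple]
    #: originating entity per column (parallel to ``columns``); lets the
    #: integrator disambiguate same-named columns from different tables
    column_entities: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise QueryError("result columns must be unique")
        for row in self.rows:
            if len(row) != len(self.columns):
                raise QueryError("result table must be rectangular")

    def column(self, name: str) -> list:
        idx = self.columns.index(name)
        return [row[idx] for row in self.rows]


class ConnectorError(RuntimeError):
    pass


class SqliteConnector:
    """Relational connector speaking SQL to an embedded database file."""

    def __init__(self, locator: str | Path):
        self.locator = str(locator)

    def run(self, sql: str) -> tuple[list[str], list[tuple]]:
        try:
            with sqlite3.connect(self.locator) as conn:
                cur = conn.execute(sql)
                columns = [d[0] for d in cur.description]
                rows = [tuple(r) for r in cur.fetchall()]
        except sqlite3.Error as exc:
            raise ConnectorError(f"relational connector failed: {exc}") from exc
        return columns, rows


class CsvConnector:
    """Flat-file connector reading RFC 4180 CSV with a header row."""

    def __init__(self, locator: str | Path):
        self.locator = str(locator)

    def scan(
        self,
        columns: Sequence[str],
        predicates: Sequence[tuple[str, object]] = (),
    ) -> tuple[list[str], list[tuple]]:
        try:
            with open(self.locator, newline="") as fh:
                reader = csv.DictReader(fh)
                if reader.fieldnames is None:
                    raise ConnectorError(f"{self.locator}: missing header row")
                missing = [c for c in columns if c not in reader.fieldnames]
                if missing:
                    raise ConnectorError(f"{self.locator}: unknown columns {missing}")
                rows = []
                for record in reader:
                    if all(str(record.get(p, "")) == str(v) for p, v in predicates):
                        rows.append(tuple(record[c] for c in columns))
        except OSError as exc:
            raise ConnectorError(f"flat-file connector failed: {exc}") from exc
        return list(columns), rows


def execute_plan(plan: QueryPlan, connector) -> ResultTable:
    """Run a plan against its source connector; rows come back sorted."""
    if plan.source_kind == "relational":
        sql = render_relational_query(plan)
        columns, rows = connector.run(sql)
    else:
        columns, rows = connector.scan(
            [c for _, c in plan.output_columns],
            [(p, lit) for _, p, lit in plan.filter_conditions],
        )
        rows.sort(key=lambda r: tuple(str(v) for v in r))
    rows = sorted(rows, key=lambda r: tuple(str(v) for v in r))
    return ResultTable(
        plan.source_id, columns, rows,
        column_entities=[e for e, _ in plan.output_columns],
    )


# ---------------------------------------------------------------------------
# the federated flow


@dataclass
class Engine:
    """Configured semantic engine: the knowledge graph plus per-source
    connectors and integration configuration."""

    graph: KnowledgeGraph
    connectors: dict[str, object]
    subject_key_paths: dict[str, str] = field(default_factory=dict)  # resource -> relative path
    identifier_equivalence: dict[object, object] = field(default_factory=dict)
    designations: dict[str, object] = field(default_factory=dict)  # fhir_path -> PrimaryDesignation
    display_datetime_format: str = "%d/%m/%Y %H:%M"

    def connector_for(self, source_id: str):
        try:
            return self.connectors[source_id]
        except KeyError:
            raise ConnectorError(f"no connector configured for source {source_id!r}") from None


@dataclass
class FederatedResult:
    query: FhirQuery
    hits: list[MappingHit]
    plans: dict[str, QueryPlan]
    rendered: dict[str, str]
    results: dict[str, ResultTable]
    annotated: dict[str, "object"]
    fhir_tables: dict[str, "object"]
    mart: "object"
    resources: list[dict]


def run_federated_query(engine: Engine, query: FhirQuery | str) -> FederatedResult:
    """Execute the full ten-step federated flow for one FHIR query."""
    from . import integrator  # late import to keep module layering acyclic

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SourceExcluded:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    if isinstance(query, str):
        query = stage("parse", parse_fhir_query, query, engine.graph)
    hits = stage("discover", discover_mappings, query, engine.graph)

    plans: dict[str, QueryPlan] = {}
    for source_id, source_hits in hits_by_source(hits).items():
        try:
            plans[source_id] = stage("plan", plan_source_query, source_hits, engine.graph, query)
        except SourceExcluded:
            continue
    if not plans:
        raise QueryError("no source can satisfy the query under its context predicates")

    rendered = {sid: stage("render", render_relational_query, plan) for sid, plan in plans.items()}
    results = {
        sid: stage("execute", execute_plan, plan, engine.connector_for(sid))
        for sid, plan in plans.items()
    }

    mappings = [mapping_spec_of(n) for n in source_registry.all_mappings(engine.graph)]
    annotated = {}
    fhir_tables = {}
    for sid, result in results.items():
        source_specs = [
            m for m in mappings
            if m.source_id == sid and _context_satisfied(m, query)
        ]
        annotated[sid] = stage("annotate", integrator.annotate_static, result, source_specs)
        fhir_tables[sid] = stage(
            "remap", integrator.remap_to_fhir, annotated[sid], source_specs, engine.graph
        )

    key_path = query.full_path(
        engine.subject_key_paths.get(query.resource_type, "subject.reference")
    )
    linked = stage(
        "link",
        integrator.link_records,
        [fhir_tables[sid] for sid in sorted(fhir_tables)],
        key_path,
        engine.identifier_equivalence,
    )
    mart = stage("integrate", integrator.row_append, linked, engine.display_datetime_format)
    resources = stage("emit", integrator.emit_fhir_resources, mart)
    return FederatedResult(
        query=query,
        hits=hits,
        plans=plans,
        rendered=rendered,
        results=results,
        annotated=annotated,
        fhir_tables=fhir_tables,
        mart=mart,
        resources=resources,
    )
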