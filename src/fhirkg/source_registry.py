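"""Registry of local data sources, their schemas, and mappings to FHIR.

Local sources (a relational database or a flat CSV file) are registered as
``Source`` nodes; their tables/files become ``Entity`` nodes and their
columns ``Property`` nodes.  A :class:`MappingSpec` relates a local property
(or a constant, or a transformed property) to a FHIR path and is stored as a
``Mapping`` node with a MAPPED_TO edge into the FHIR schema graph and — for
DIRECT/TRANSFORM mappings — a MAPPED_FROM edge to the local property.

Mapping identity is a deterministic content hash, so re-registering the same
declaration is idempotent and registry builds are order-independent.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import fhir_schema
from .graph_store import GraphError, KnowledgeGraph, GraphNode, stable_id

SOURCE_KINDS = frozenset({"relational", "flat_file"})
MAPPING_KINDS = frozenset({"DIRECT", "STATIC", "TRANSFORM"})
TRANSFORM_KINDS = frozenset({"linear_unit", "datetime_reformat"})


class RegistryError(ValueError):
    """Invalid registration or mapping declaration."""


# ---------------------------------------------------------------------------
# declarations


@dataclass(frozen=True)
class SourceDescriptor:
    source_id: str
    kind: str  # relational | flat_file
    connection: str  # file path / embedded-database locator
    primary_for: frozenset[str] = frozenset()  # FHIR paths this source is authoritative for

    def __post_init__(self) -> None:
        if self.kind not in SOURCE_KINDS:
            raise RegistryError(f"unknown source kind {self.kind!r}")


@dataclass(frozen=True)
class LocalPropertyDef:
    source_id: str
    entity_name: str
    property_name: str
    value_type: str = "string"
    datetime_format: str | None = None


@dataclass(frozen=True)
class MappingSpec:
    fhir_path: str
    kind: str  # DIRECT | STATIC | TRANSFORM
    local_ref: tuple[str, str, str] | None = None  # (source_id, entity, property)
    static_value: object = None
    transform_id: str | None = None
    source_id: str | None = None  # required for STATIC (no local_ref to carry it)
    context: tuple[tuple[str, str], ...] = ()  # conjunction of (fhir_path, literal)

    def __post_init__(self) -> None:
        if self.kind not in MAPPING_KINDS:
            raise RegistryError(f"unknown mapping kind {self.kind!r}")
        if self.kind == "STATIC":
            if self.local_ref is not None:
                raise RegistryError("STATIC mapping must not carry a local_ref")
            if self.static_value is None:
                raise RegistryError("STATIC mapping requires a static_value")
            if self.source_id is None:
                raise RegistryError("STATIC mapping requires a source_id")
        else:
            if self.local_ref is None:
                raise RegistryError(f"{self.kind} mapping requires a local_ref")
            if self.static_value is not None:
                raise RegistryError(f"{self.kind} mapping must not carry a static_value")
            if self.kind == "TRANSFORM" and not self.transform_id:
                raise RegistryError("TRANSFORM mapping requires a transform_id")
        if self.local_ref is not None and self.source_id is None:
            object.__setattr__(self, "source_id", self.local_ref[0])

    @property
    def mapping_id(self) -> str:
        payload = json.dumps(
            [
                self.fhir_path, self.kind, self.local_ref, self.static_value,
                self.transform_id, self.source_id, self.context,
            ],
            sort_keys=True, default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TransformSpec:
    transform_id: str
    kind: str  # linear_unit | datetime_reformat
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise RegistryError(f"unknown transform kind {self.kind!r}")
        if self.kind == "linear_unit" and float(self.params.get("factor", 0)) == 0:
            raise RegistryError("linear_unit transform requires a non-zero factor")
        if self.kind == "datetime_reformat" and not (
            self.params.get("source_format") and self.params.get("target_format")
        ):
            raise RegistryError("datetime_reformat requires source_format and target_format")


@dataclass(frozen=True)
class InternalJoin:
    source_id: str
    left: tuple[str, str]  # (entity, property)
    right: tuple[str, str]


# ---------------------------------------------------------------------------
# qualified names for local nodes


def source_qname(source_id: str) -> str:
    return f"src.{source_id}"


def local_entity_qname(source_id: str, entity: str) -> str:
    return f"local.{source_id}.{entity}"


def local_property_qname(source_id: str, entity: str, prop: str) -> str:
    return f"local.{source_id}.{entity}.{prop}"


# ---------------------------------------------------------------------------
# registration operations


def register_source(desc: SourceDescriptor, graph: KnowledgeGraph) -> str:
    existing = graph.find_nodes("Source", {"source_id": desc.source_id})
    if existing:
        raise RegistryError(f"source_id {desc.source_id!r} already registered")
    return graph.add_node(
        "Source",
        {
            "source_id": desc.source_id,
            "qualified_name": source_qname(desc.source_id),
            "kind": desc.kind,
            "connection": desc.connection,
            "primary_for": ";".join(sorted(desc.primary_for)),
        },
    )


def _source_node(graph: KnowledgeGraph, source_id: str) -> GraphNode:
    nodes = graph.find_nodes("Source", {"source_id": source_id})
    if not nodes:
        raise RegistryError(f"unknown source {source_id!r}")
    return nodes[0]


def _add_local_entity(graph: KnowledgeGraph, source_id: str, entity: str) -> str:
    qname = local_entity_qname(source_id, entity)
    eid = stable_id("Entity", qname)
    if eid not in graph:
        graph.add_node(
            "Entity",
            {"name": entity, "qualified_name": qname, "kind": "local", "source_id": source_id},
        )
        graph.add_edge(_source_node(graph, source_id).node_id, eid, "HAS_ENTITY")
    return eid


def _add_local_property(graph: KnowledgeGraph, col: LocalPropertyDef) -> str:
    qname = local_property_qname(col.source_id, col.entity_name, col.property_name)
    pid = stable_id("Property", qname)
    if pid not in graph:
        eid_parent = stable_id("Entity", local_entity_qname(col.source_id, col.entity_name))
        ordinal = len(graph.neighbors(eid_parent, relation="HAS_PROPERTY", direction="out"))
        attrs = {
            "name": col.property_name,
            "qualified_name": qname,
            "kind": "local",
            "source_id": col.source_id,
            "entity": col.entity_name,
            "value_type": col.value_type,
            "ordinal": ordinal,  # declaration order within the entity
        }
        if col.datetime_format:
            attrs["datetime_format"] = col.datetime_format
        graph.add_node("Property", attrs)
        eid = stable_id("Entity", local_entity_qname(col.source_id, col.entity_name))
        graph.add_edge(eid, pid, "HAS_PROPERTY")
    return pid


def import_relational_schema(
    source_id: str,
    tables: Mapping[str, Sequence[LocalPropertyDef]],
    graph: KnowledgeGraph,
) -> dict[str, int]:
    """Import a relational schema listing: Entity node per table, Property per column."""
    src = _source_node(graph, source_id)
    if src["kind"] != "relational":
        raise RegistryError(f"source {source_id!r} is not relational")
    counts = {"entities": 0, "properties": 0}
    for table in sorted(tables):
        before = graph.node_count
        _add_local_entity(graph, source_id, table)
        counts["entities"] += graph.node_count - before
        for col in tables[table]:
            if (col.source_id, col.entity_name) != (source_id, table):
                raise RegistryError(
                    f"column {col.property_name!r} declared under wrong table "
                    f"({col.source_id}.{col.entity_name} != {source_id}.{table})"
                )
            before = graph.node_count
            _add_local_property(graph, col)
            counts["properties"] += graph.node_count - before
    return counts


def declare_flat_schema(
    source_id: str, columns: Sequence[LocalPropertyDef], graph: KnowledgeGraph
) -> dict[str, int]:
    """Declare the (single-entity) schema of a flat file source."""
    src = _source_node(graph, source_id)
    if src["kind"] != "flat_file":
        raise RegistryError(f"source {source_id!r} is not a flat file")
    if not columns:
        raise RegistryError("flat-file schema requires at least one column")
    entities = {c.entity_name for c in columns}
    if len(entities) != 1:
        raise RegistryError("flat-file schema must declare exactly one logical entity")
    names = [c.property_name for c in columns]
    if len(set(names)) != len(names):
        raise RegistryError("duplicate column names in flat-file schema")
    entity = columns[0].entity_name
    counts = {"entities": 0, "properties": 0}
    before = graph.node_count
    _add_local_entity(graph, source_id, entity)
    counts["entities"] = graph.node_count - before
    for col in columns:
        before = graph.node_count
        _add_local_property(graph, col)
        counts["properties"] += graph.node_count - before
    return counts


def add_mapping(spec: MappingSpec, graph: KnowledgeGraph) -> str:
    """Store a mapping declaration as a Mapping node with its edges.

    Idempotent: the node id is the content hash of the spec, so adding the
    same spec twice returns the same id and changes nothing.
    """
    fhir_node = fhir_schema.resolve_path(graph, spec.fhir_path)  # raises if unresolved
    local_pid = None
    if spec.local_ref is not None:
        qname = local_property_qname(*spec.local_ref)
        local_pid = stable_id("Property", qname)
        if local_pid not in graph:
            raise RegistryError(f"local property {qname!r} is not registered")
    for ctx_path, _ in spec.context:
        fhir_schema.resolve_path(graph, ctx_path)
    mapping_qname = f"mapping.{spec.mapping_id}"
    mid = stable_id("Mapping", mapping_qname)
    if mid in graph:
        return mid
    attrs = {
        "mapping_id": spec.mapping_id,
        "qualified_name": mapping_qname,
        "fhir_path": spec.fhir_path,
        "map_kind": spec.kind,
        "source_id": spec.source_id or "",
    }
    if spec.local_ref is not None:
        attrs["entity"] = spec.local_ref[1]
        attrs["property"] = spec.local_ref[2]
    if spec.static_value is not None:
        attrs["static_value"] = spec.static_value
    if spec.transform_id:
        attrs["transform_id"] = spec.transform_id
    if spec.context:
        attrs["context"] = json.dumps(sorted(spec.context), default=str)
    graph.add_node("Mapping", attrs, node_id=mid)
    graph.add_edge(mid, fhir_node.node_id, "MAPPED_TO")
    if local_pid is not None:
        graph.add_edge(mid, local_pid, "MAPPED_FROM")
    return mid


def mapping_spec_of(node: GraphNode) -> MappingSpec:
    """Reconstruct the MappingSpec payload from a Mapping node."""
    local_ref = None
    if "entity" in node.attrs:
        local_ref = (node["source_id"], node["entity"], node["property"])
    context: tuple[tuple[str, str], ...] = ()
    if "context" in node.attrs:
        context = tuple(tuple(pair) for pair in json.loads(node["context"]))
    return MappingSpec(
        fhir_path=node["fhir_path"],
        kind=node["map_kind"],
        local_ref=local_ref,
        static_value=node.get("static_value"),
        transform_id=node.get("transform_id"),
        source_id=node["source_id"] or None,
        context=context,
    )


def add_transform(spec: TransformSpec, graph: KnowledgeGraph) -> None:
    transforms = graph.meta.setdefault("transforms", {})
    transforms[spec.transform_id] = {"kind": spec.kind, "params": dict(spec.params)}


def get_transform(graph: KnowledgeGraph, transform_id: str) -> TransformSpec:
    try:
        raw = graph.meta["transforms"][transform_id]
    except KeyError:
        raise RegistryError(f"unknown transform {transform_id!r}") from None
    return TransformSpec(transform_id, raw["kind"], raw["params"])


def add_internal_join(join: InternalJoin, graph: KnowledgeGraph) -> tuple[str, str]:
    """Declare an intra-source join between two local properties (JOINS edge)."""
    if join.left == join.right:
        raise RegistryError("cannot join a column to itself")
    pids = []
    for entity, prop in (join.left, join.right):
        qname = local_property_qname(join.source_id, entity, prop)
        pid = stable_id("Property", qname)
        if pid not in graph:
            raise RegistryError(f"join endpoint {qname!r} is not registered")
        if graph.node(pid)["source_id"] != join.source_id:
            raise RegistryError("joins must be intra-source")
        pids.append(pid)
    a, b = sorted(pids)
    try:
        graph.add_edge(a, b, "JOINS", {"source_id": join.source_id})
    except GraphError:
        pass  # idempotent
    return (a, b)


def iter_joins(graph: KnowledgeGraph, source_id: str) -> list[InternalJoin]:
    out = []
    for edge in graph.edges():
        if edge.relation != "JOINS" or edge.attrs.get("source_id") != source_id:
            continue
        left = graph.node(edge.from_id)
        right = graph.node(edge.to_id)
        out.append(
            InternalJoin(
                source_id,
                (left["entity"], left["name"]),
                (right["entity"], right["name"]),
            )
        )
    return out


def entity_columns(graph: KnowledgeGraph, source_id: str, entity: str) -> list[GraphNode]:
    """Property nodes of a local entity in declaration order."""
    eid = stable_id("Entity", local_entity_qname(source_id, entity))
    if eid not in graph:
        raise RegistryError(f"unknown entity {source_id}.{entity}")
    props = graph.neighbors(eid, relation="HAS_PROPERTY", direction="out")
    return sorted(props, key=lambda n: (n.get("ordinal", 0), n["name"]))


def local_property_node(graph: KnowledgeGraph, source_id: str, entity: str, prop: str) -> GraphNode:
    pid = stable_id("Property", local_property_qname(source_id, entity, prop))
    if pid not in graph:
        raise RegistryError(f"unknown local property {source_id}.{entity}.{prop}")
    return graph.node(pid)


def all_mappings(graph: KnowledgeGraph) -> list[GraphNode]:
    return graph.find_nodes("Mapping")


def primary_paths(graph: KnowledgeGraph, source_id: str) -> set[str]:
    node = _source_node(graph, source_id)
    raw = node.get("primary_for", "")
    return set(p for p in raw.split(";") if p)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ConflictAlert:
    kind: str  # multiple_source_unresolved | value_mismatch | unit_mismatch | double_mapping
    fhir_path: str
    details: tuple[tuple, ...]  # (source_id, entity, property, optional value)
    subject_key: object = None


def validate_registry(graph: KnowledgeGraph) -> list[ConflictAlert]:
    """Check the mapping registry for inconsistencies.

    Alerts (never errors) are raised for:
    (a) a FHIR path backed by two or more distinct local refs with no source
        designated primary for it;
    (b) one local property mapped to two or more FHIR paths;
    (c) unit disagreement between mappings of one path when neither side
        declares a TRANSFORM.
    """
    alerts: list[ConflictAlert] = []
    mappings = [mapping_spec_of(n) for n in all_mappings(graph)]

    by_path: dict[str, list[MappingSpec]] = {}
    for spec in mappings:
        by_path.setdefault(spec.fhir_path, []).append(spec)
    for path in sorted(by_path):
        specs = [s for s in by_path[path] if s.local_ref is not None]
        refs = sorted({s.local_ref for s in specs})
        if len(refs) >= 2:
            covered = any(
                path in primary_paths(graph, sid)
                for sid in sorted({r[0] for r in refs})
            )
            if not covered:
                alerts.append(
                    ConflictAlert(
                        kind="multiple_source_unresolved",
                        fhir_path=path,
                        details=tuple(refs),
                    )
                )

    by_ref: dict[tuple, list[MappingSpec]] = {}
    for spec in mappings:
        if spec.local_ref is not None:
            by_ref.setdefault(spec.local_ref, []).append(spec)
    for ref in sorted(by_ref):
        paths = sorted({s.fhir_path for s in by_ref[ref]})
        if len(paths) >= 2:
            alerts.append(
                ConflictAlert(
                    kind="double_mapping",
                    fhir_path=";".join(paths),
                    details=(ref,),
                )
            )

    # (c) unit mismatch: DIRECT mappings of one path whose local columns declare
    # different unit annotations and no TRANSFORM mapping bridges them
    for path in sorted(by_path):
        units: dict[str, tuple] = {}
        has_transform = any(s.kind == "TRANSFORM" for s in by_path[path])
        for spec in by_path[path]:
            if spec.local_ref is None or spec.kind != "DIRECT":
                continue
            qname = local_property_qname(*spec.local_ref)
            node = graph.node(stable_id("Property", qname))
            unit = node.get("unit")
            if unit:
                units[unit] = spec.local_ref
        if len(units) >= 2 and not has_transform:
            alerts.append(
                ConflictAlert(
                    kind="unit_mismatch",
                    fhir_path=path,
                    details=tuple(sorted(units.values())),
                )
            )
    return alerts


# ---------------------------------------------------------------------------
# batch declaration formats

MAPPING_CSV_COLUMNS = [
    "fhir_path", "kind", "source_id", "entity", "property",
    "static_value", "transform_id", "context",
]


def _coerce_literal(text: str) -> object:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def _parse_context(text: str) -> tuple[tuple[str, str], ...]:
    # "path=literal;path=literal"
    if not text:
        return ()
    pairs = []
    for clause in text.split(";"):
        if "=" not in clause:
            raise RegistryError(f"malformed context clause {clause!r}")
        path, literal = clause.split("=", 1)
        pairs.append((path.strip(), literal.strip()))
    return tuple(pairs)


def load_mapping_csv(text: str) -> list[MappingSpec]:
    """Parse batch mapping declarations from CSV text (header row required)."""
    reader = csv.DictReader(io.StringIO(text))
    missing = set(MAPPING_CSV_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise RegistryError(f"mapping CSV missing columns: {sorted(missing)}")
    specs = []
    for row in reader:
        kind = row["kind"].strip().upper()
        local_ref = None
        if row["entity"].strip():
            local_ref = (row["source_id"].strip(), row["entity"].strip(), row["property"].strip())
        specs.append(
            MappingSpec(
                fhir_path=row["fhir_path"].strip(),
                kind=kind,
                local_ref=local_ref,
                static_value=_coerce_literal(row["static_value"].strip()) if row["static_value"].strip() else None,
                transform_id=row["transform_id"].strip() or None,
                source_id=row["source_id"].strip() or None,
                context=_parse_context(row["context"].strip()),
            )
        )
    return specs


def dump_mapping_csv(specs: Iterable[MappingSpec]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=MAPPING_CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for spec in specs:
        writer.writerow(
            {
                "fhir_path": spec.fhir_path,
                "kind": spec.kind,
                "source_id": spec.source_id or "",
                "entity": spec.local_ref[1] if spec.local_ref else "",
                "property": spec.local_ref[2] if spec.local_ref else "",
                "static_value": "" if spec.static_value is None else spec.static_value,
                "transform_id": spec.transform_id or "",
                "context": ";".join(f"{p}={v}" for p, v in spec.context),
            }
        )
    return buf.getvalue()


def load_mapping_yaml(text: str) -> list[MappingSpec]:
    """YAML alternative to the CSV batch format: a list of mapping objects."""
    data = yaml.safe_load(text) or []
    specs = []
    for item in data:
        local_ref = None
        if item.get("entity"):
            local_ref = (item["source_id"], item["entity"], item["property"])
        context = tuple(
            (clause["path"], str(clause["value"])) for clause in item.get("context", [])
        )
        specs.append(
            MappingSpec(
                fhir_path=item["fhir_path"],
                kind=item["kind"].upper(),
                local_ref=local_ref,
                static_value=item.get("static_value"),
                transform_id=item.get("transform_id"),
                source_id=item.get("source_id"),
                context=context,
            )
        )
    return specs
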