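"""Parse FHIR resource definitions and materialise them as graph nodes.

The input dialect is a simplified FHIR-like JSON document: a top-level object
mapping resource names to ``{"description": ..., "properties": {...}}``, where
each property is ``{"type": ..., "cardinality": "single"|"many",
"description": ..., "target": <resource>}`` and complex properties nest a
``properties`` object of their own.  Nested sub-objects are flattened into
dotted paths (``Observation.coding.code``), mirroring how each sub-object of a
resource becomes its own Property node in the knowledge graph.

Qualified names in the graph are ``FHIR.<Resource>`` for Entity nodes and
``FHIR.<Resource>.<dotted.path>`` for Property nodes, so node ids are stable
across rebuilds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .graph_store import KnowledgeGraph, GraphNode, stable_id

#: FHIR primitive types the fixture dialect recognises; anything else is kept
#: but recorded as a warning (complex types are expressed by nesting instead).
KNOWN_VALUE_TYPES = frozenset(
    {
        "string", "code", "id", "boolean", "integer", "decimal",
        "date", "dateTime", "instant", "uri", "Reference", "object",
    }
)


class SchemaError(ValueError):
    """Malformed resource-definition document or unresolvable path."""


@dataclass(frozen=True)
class FhirPropertyDef:
    name: str  # dotted, relative to the resource (e.g. "coding.code")
    value_type: str
    cardinality: str = "single"  # single | many
    description: str = ""


@dataclass
class FhirResourceDef:
    name: str
    category: str = "fixture"
    properties: list[FhirPropertyDef] = field(default_factory=list)
    references: list[tuple[str, str]] = field(default_factory=list)  # (property, target resource)

    def property_names(self) -> list[str]:
        return [p.name for p in self.properties]


@dataclass
class BuildReport:
    entity_nodes: int = 0
    property_nodes: int = 0
    edges: int = 0


def fhir_entity_qname(resource: str) -> str:
    return f"FHIR.{resource}"


def fhir_property_qname(resource: str, dotted: str) -> str:
    return f"FHIR.{resource}.{dotted}"


def parse_resource_definitions(doc: str, warnings: list[str] | None = None) -> list[FhirResourceDef]:
    """Parse a resource-definition JSON document into FhirResourceDef objects.

    Every defined entity yields exactly one definition; nested sub-objects
    become dotted properties, so the parse is total (no silent drops).
    Unknown value types are recorded in ``warnings`` but the property is kept.
    """
    try:
        data = json.loads(doc)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON at line {exc.lineno} column {exc.colno}: {exc.msg}") from exc
    if not isinstance(data, dict):
        raise SchemaError("top level must be an object of resource definitions")
    defs = []
    for name in data:
        body = data[name]
        if not isinstance(body, dict):
            raise SchemaError(f"resource {name!r} must be an object")
        resource = FhirResourceDef(name=name, category=body.get("category", "fixture"))
        _flatten_properties(name, "", body.get("properties", {}), resource, warnings)
        defs.append(resource)
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate resource names in definition document")
    return defs


def _flatten_properties(
    resource: str,
    prefix: str,
    props: dict,
    out: FhirResourceDef,
    warnings: list[str] | None,
) -> None:
    if not isinstance(props, dict):
        raise SchemaError(f"properties of {resource}.{prefix or ''} must be an object")
    for pname, body in props.items():
        if not pname:
            raise SchemaError(f"empty property name under {resource}.{prefix}")
        dotted = f"{prefix}.{pname}" if prefix else pname
        body = body or {}
        vtype = body.get("type", "object" if "properties" in body else "string")
        if vtype not in KNOWN_VALUE_TYPES and warnings is not None:
            warnings.append(f"unknown value_type {vtype!r} for {resource}.{dotted}")
        out.properties.append(
            FhirPropertyDef(
                name=dotted,
                value_type=vtype,
                cardinality=body.get("cardinality", "single"),
                description=body.get("description", ""),
            )
        )
        if "target" in body:
            out.references.append((dotted, body["target"]))
        if "properties" in body:
            _flatten_properties(resource, dotted, body["properties"], out, warnings)


def build_knowledge_graph(defs: list[FhirResourceDef], graph: KnowledgeGraph) -> BuildReport:
    """Materialise parsed definitions as Entity/Property nodes and edges.

    Idempotent: rebuilding from the same definitions adds nothing.  Cross-
    resource references become REFERENCES edges from the referring Property
    node to the target Entity node; a dangling target raises.
    """
    report = BuildReport()
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise SchemaError("name collision between resource definitions")
    # entities first so references can resolve regardless of defs order
    for rdef in sorted(defs, key=lambda d: d.name):
        eid = stable_id("Entity", fhir_entity_qname(rdef.name))
        if eid not in graph:
            graph.add_node(
                "Entity",
                {
                    "name": rdef.name,
                    "qualified_name": fhir_entity_qname(rdef.name),
                    "kind": "fhir",
                    "category": rdef.category,
                },
            )
            report.entity_nodes += 1
    for rdef in sorted(defs, key=lambda d: d.name):
        eid = stable_id("Entity", fhir_entity_qname(rdef.name))
        for prop in rdef.properties:
            qname = fhir_property_qname(rdef.name, prop.name)
            pid = stable_id("Property", qname)
            if pid not in graph:
                graph.add_node(
                    "Property",
                    {
                        "name": prop.name.rsplit(".", 1)[-1],
                        "qualified_name": qname,
                        "kind": "fhir",
                        "resource": rdef.name,
                        "path": f"{rdef.name}.{prop.name}",
                        "value_type": prop.value_type,
                        "cardinality": prop.cardinality,
                    },
                )
                report.property_nodes += 1
                graph.add_edge(eid, pid, "HAS_PROPERTY")
                report.edges += 1
        for prop_name, target in rdef.references:
            tid = stable_id("Entity", fhir_entity_qname(target))
            if tid not in graph:
                raise SchemaError(
                    f"reference {rdef.name}.{prop_name} targets unknown resource {target!r}"
                )
            pid = stable_id("Property", fhir_property_qname(rdef.name, prop_name))
            if not any(
                e.to_id == tid and e.relation == "REFERENCES"
                for e in graph.edges_of(pid, relation="REFERENCES", direction="out")
            ):
                graph.add_edge(pid, tid, "REFERENCES")
                report.edges += 1
    return report


def resolve_path(graph: KnowledgeGraph, path: str) -> GraphNode:
    """Resolve a dotted FHIR path to its Property (or Entity root) node.

    Case-sensitive.  Raises :class:`SchemaError` naming the first segment
    that fails to resolve.
    """
    segments = path.split(".")
    root = segments[0]
    entity_id = stable_id("Entity", fhir_entity_qname(root))
    if entity_id not in graph:
        raise SchemaError(f"path {path!r}: unknown resource {root!r}")
    if len(segments) == 1:
        return graph.node(entity_id)
    # check each prefix so the error names the failing segment
    for i in range(2, len(segments) + 1):
        qname = fhir_property_qname(root, ".".join(segments[1:i]))
        pid = stable_id("Property", qname)
        if pid not in graph:
            raise SchemaError(f"path {path!r}: segment {segments[i - 1]!r} does not resolve")
    return graph.node(pid)


@dataclass
class PathTopology:
    """1-hop explanation bundle for a FHIR path: the node, its parent chain
    up to the resource root, and every Mapping node attached to it."""

    node: GraphNode
    parents: list[GraphNode]
    mappings: list[GraphNode]
    neighbors: list[tuple[str, GraphNode]]  # (relation, node), both directions


def describe_path(graph: KnowledgeGraph, path: str) -> PathTopology:
    node = resolve_path(graph, path)
    segments = path.split(".")
    parents: list[GraphNode] = []
    if len(segments) > 1:
        for i in range(len(segments) - 1, 1, -1):
            qname = fhir_property_qname(segments[0], ".".join(segments[1:i]))
            pid = stable_id("Property", qname)
            if pid in graph:
                parents.append(graph.node(pid))
        parents.append(graph.node(stable_id("Entity", fhir_entity_qname(segments[0]))))
    mappings = [
        n for n in graph.neighbors(node.node_id, relation="MAPPED_TO", direction="in")
        if n.label == "Mapping"
    ]
    neighbor_pairs: list[tuple[str, GraphNode]] = []
    for edge in graph.edges_of(node.node_id):
        other = edge.to_id if edge.from_id == node.node_id else edge.from_id
        neighbor_pairs.append((edge.relation, graph.node(other)))
    neighbor_pairs.sort(key=lambda pair: (pair[0], pair[1].node_id))
    return PathTopology(node=node, parents=parents, mappings=mappings, neighbors=neighbor_pairs)
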