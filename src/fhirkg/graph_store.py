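"""In-process property-graph store for the FHIR knowledge graph.

The graph holds four node labels (``Source``, ``Entity``, ``Property``,
``Mapping``) and a fixed edge-relation vocabulary.  It is the substrate both
for the FHIR schema graph (entities, properties, references) and for the
schema-mapping graph that links local data sources to FHIR paths.

The store is deliberately server-less: it wraps a :class:`networkx.MultiDiGraph`
and adds label/relation validation, duplicate-edge rejection, deterministic
ordering (everything is sorted by ``node_id``) and two text exports — a
Cypher-dialect script and a line-delimited JSON dump — either of which
round-trips to an identical graph.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Any, Mapping

import networkx as nx

NODE_LABELS = frozenset({"Source", "Entity", "Property", "Mapping"})
EDGE_RELATIONS = frozenset(
    {"HAS_ENTITY", "HAS_PROPERTY", "REFERENCES", "MAPPED_FROM", "MAPPED_TO", "JOINS"}
)

Scalar = str | int | float | bool


class GraphError(ValueError):
    """Raised on any violation of the graph's structural contract."""


def stable_id(label: str, qualified_name: str) -> str:
    """Deterministic node id derived from (label, qualified name).

    Declaratively-created nodes (schema imports, mapping registrations) use
    this so that repeated builds of the same registry produce byte-identical
    graphs.
    """
    digest = hashlib.sha1(f"{label}|{qualified_name}".encode()).hexdigest()
    return digest[:12]


@dataclass(frozen=True)
class GraphNode:
    node_id: str
    label: str
    attrs: Mapping[str, Scalar]

    def __getitem__(self, key: str) -> Scalar:
        return self.attrs[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.attrs.get(key, default)


@dataclass(frozen=True)
class GraphEdge:
    from_id: str
    to_id: str
    relation: str
    attrs: Mapping[str, Scalar] = field(default_factory=dict)


def _check_attrs(attrs: Mapping[str, Any]) -> dict[str, Scalar]:
    out: dict[str, Scalar] = {}
    for key, value in attrs.items():
        if not isinstance(key, str) or not key:
            raise GraphError(f"attribute keys must be non-empty text, got {key!r}")
        if not isinstance(value, (str, int, float, bool)):
            raise GraphError(
                f"attribute {key!r} must be a scalar (text/number/boolean), got {type(value).__name__}"
            )
        out[key] = value
    return out


class KnowledgeGraph:
    """Label/attribute property graph with pattern search and traversal."""

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._edge_triples: set[tuple[str, str, str]] = set()
        #: free-form graph-level metadata (e.g. registered transform specs);
        #: scalars/dicts only, carried through the JSONL dump.
        self.meta: dict[str, Any] = {}

    # -- mutation ---------------------------------------------------------

    def add_node(
        self,
        label: str,
        attrs: Mapping[str, Scalar] | None = None,
        node_id: str | None = None,
    ) -> str:
        if label not in NODE_LABELS:
            raise GraphError(
                f"unknown node label {label!r}; expected one of {sorted(NODE_LABELS)}"
            )
        attrs = _check_attrs(attrs or {})
        if node_id is None:
            qname = attrs.get("qualified_name")
            if qname is not None:
                node_id = stable_id(label, str(qname))
            else:
                # content-derived id; disambiguate genuine duplicates
                base = hashlib.sha1(
                    json.dumps([label, sorted(attrs.items())], default=str).encode()
                ).hexdigest()[:12]
                node_id = base
                suffix = 1
                while node_id in self._g:
                    node_id = f"{base}-{suffix}"
                    suffix += 1
        if node_id in self._g:
            raise GraphError(f"node id {node_id!r} already present")
        self._g.add_node(node_id, label=label, attrs=attrs)
        return node_id

    def add_edge(
        self,
        from_id: str,
        to_id: str,
        relation: str,
        attrs: Mapping[str, Scalar] | None = None,
    ) -> GraphEdge:
        if relation not in EDGE_RELATIONS:
            raise GraphError(
                f"unknown relation {relation!r}; expected one of {sorted(EDGE_RELATIONS)}"
            )
        for endpoint in (from_id, to_id):
            if endpoint not in self._g:
                raise GraphError(f"edge endpoint {endpoint!r} does not exist")
        triple = (from_id, to_id, relation)
        if triple in self._edge_triples:
            raise GraphError(f"duplicate edge {from_id}-[{relation}]->{to_id}")
        attrs = _check_attrs(attrs or {})
        self._g.add_edge(from_id, to_id, key=relation, attrs=attrs)
        self._edge_triples.add(triple)
        return GraphEdge(from_id, to_id, relation, attrs)

    # -- access -----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    @property
    def node_count(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return len(self._edge_triples)

    def node(self, node_id: str) -> GraphNode:
        if node_id not in self._g:
            raise GraphError(f"unknown node {node_id!r}")
        data = self._g.nodes[node_id]
        return GraphNode(node_id, data["label"], dict(data["attrs"]))

    def nodes(self) -> list[GraphNode]:
        return [self.node(n) for n in sorted(self._g.nodes)]

    def edges(self) -> list[GraphEdge]:
        out = []
        for u, v, key, data in self._g.edges(keys=True, data=True):
            out.append(GraphEdge(u, v, key, dict(data["attrs"])))
        out.sort(key=lambda e: (e.from_id, e.to_id, e.relation))
        return out

    def find_nodes(
        self, label: str | None = None, predicate: Mapping[str, Scalar] | None = None
    ) -> list[GraphNode]:
        """All nodes matching ``label`` and every attribute equality, sorted by id."""
        predicate = predicate or {}
        hits = []
        for node_id in sorted(self._g.nodes):
            data = self._g.nodes[node_id]
            if label is not None and data["label"] != label:
                continue
            attrs = data["attrs"]
            if all(attrs.get(k) == v for k, v in predicate.items()):
                hits.append(GraphNode(node_id, data["label"], dict(attrs)))
        return hits

    def neighbors(
        self,
        node_id: str,
        relation: str | None = None,
        direction: str = "out",
    ) -> list[GraphNode]:
        """Adjacent nodes along ``relation`` in ``direction`` (out/in/both), sorted."""
        if node_id not in self._g:
            raise GraphError(f"unknown node {node_id!r}")
        if direction not in {"out", "in", "both"}:
            raise GraphError(f"direction must be out/in/both, got {direction!r}")
        ids: set[str] = set()
        if direction in {"out", "both"}:
            for _, v, key in self._g.out_edges(node_id, keys=True):
                if relation is None or key == relation:
                    ids.add(v)
        if direction in {"in", "both"}:
            for u, _, key in self._g.in_edges(node_id, keys=True):
                if relation is None or key == relation:
                    ids.add(u)
        return [self.node(n) for n in sorted(ids)]

    def edges_of(
        self, node_id: str, relation: str | None = None, direction: str = "both"
    ) -> list[GraphEdge]:
        out = []
        for edge in self.edges():
            if relation is not None and edge.relation != relation:
                continue
            if direction in {"out", "both"} and edge.from_id == node_id:
                out.append(edge)
            elif direction in {"in", "both"} and edge.to_id == node_id:
                out.append(edge)
        return out

    # -- export / import --------------------------------------------------

    def export_script(self) -> str:
        """Cypher-dialect script: one CREATE per node, then one per edge.

        Node statements are sorted by node_id, edge statements by
        (from, to, relation); re-importing via :func:`import_script`
        reproduces an identical graph, so export-import-export is a fixpoint.
        """
        lines = []
        for node in self.nodes():
            props = _cypher_props({"node_id": node.node_id, **node.attrs})
            lines.append(f"CREATE (:{node.label} {props});")
        for edge in self.edges():
            props = _cypher_props(edge.attrs)
            rel = f"[:{edge.relation} {props}]" if edge.attrs else f"[:{edge.relation}]"
            lines.append(
                f'MATCH (a {{node_id: "{edge.from_id}"}}), (b {{node_id: "{edge.to_id}"}}) '
                f"CREATE (a)-{rel}->(b);"
            )
        return "".join(line + "\n" for line in lines)

    def to_jsonl(self) -> str:
        """Line-delimited JSON dump (one node or edge object per line)."""
        lines = []
        if self.meta:
            lines.append(json.dumps({"type": "meta", "meta": self.meta}, sort_keys=True))
        for node in self.nodes():
            lines.append(
                json.dumps(
                    {"type": "node", "id": node.node_id, "label": node.label, "attrs": dict(node.attrs)},
                    sort_keys=True,
                )
            )
        for edge in self.edges():
            lines.append(
                json.dumps(
                    {
                        "type": "edge",
                        "from": edge.from_id,
                        "to": edge.to_id,
                        "relation": edge.relation,
                        "attrs": dict(edge.attrs),
                    },
                    sort_keys=True,
                )
            )
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_jsonl(cls, text: str) -> "KnowledgeGraph":
        graph = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            if obj["type"] == "meta":
                graph.meta = obj["meta"]
            elif obj["type"] == "node":
                graph.add_node(obj["label"], obj["attrs"], node_id=obj["id"])
            else:
                graph.add_edge(obj["from"], obj["to"], obj["relation"], obj["attrs"])
        return graph


_NODE_RE = re.compile(r"^CREATE \(:(\w+) (\{.*\})\);$")
_EDGE_RE = re.compile(
    r'^MATCH \(a \{node_id: "([^"]+)"\}\), \(b \{node_id: "([^"]+)"\}\) '
    r"CREATE \(a\)-\[:(\w+)(?: (\{.*\}))?\]->\(b\);$"
)


def _cypher_props(attrs: Mapping[str, Scalar]) -> str:
    # property maps are emitted with quoted keys (valid Cypher, and plain JSON,
    # so values containing colons survive re-import)
    parts = []
    for key in sorted(attrs):
        parts.append(f"{json.dumps(key)}: {json.dumps(attrs[key])}")
    return "{" + ", ".join(parts) + "}"


def _parse_props(text: str) -> dict[str, Scalar]:
    return json.loads(text)


def import_script(text: str) -> KnowledgeGraph:
    """Rebuild a graph from the Cypher-dialect text produced by export_script."""
    graph = KnowledgeGraph()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _NODE_RE.match(line)
        if m:
            label, props = m.group(1), _parse_props(m.group(2))
            node_id = str(props.pop("node_id"))
            graph.add_node(label, props, node_id=node_id)
            continue
        m = _EDGE_RE.match(line)
        if m:
            from_id, to_id, relation = m.group(1), m.group(2), m.group(3)
            attrs = _parse_props(m.group(4)) if m.group(4) else {}
            graph.add_edge(from_id, to_id, relation, attrs)
            continue
        raise GraphError(f"unparseable statement: {line!r}")
    return graph


def isomorphic_content(a: KnowledgeGraph, b: KnowledgeGraph) -> bool:
    """Content equality on (id, label, attrs) node sets and edge triples."""

    def node_set(g: KnowledgeGraph) -> set[tuple]:
        return {
            (n.node_id, n.label, tuple(sorted(n.attrs.items()))) for n in g.nodes()
        }

    def edge_set(g: KnowledgeGraph) -> set[tuple]:
        return {
            (e.from_id, e.to_id, e.relation, tuple(sorted(e.attrs.items())))
            for e in g.edges()
        }

    return node_set(a) == node_set(b) and edge_set(a) == edge_set(b)
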