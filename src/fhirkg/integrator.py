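"""Convert per-source query results into unified FHIR-format output.

The pipeline stages here mirror the integration half of the federated flow:

1. ``annotate_static`` — append constant semantic columns (STATIC mappings)
   to a sparse source's result, e.g. giving a two-column glucose file its
   patient reference, LOINC code and unit.
2. ``remap_to_fhir`` — rename mapped local columns to their FHIR paths,
   apply any transformation functions embedded in the mappings, and drop
   every unmapped column.
3. ``link_records`` — harmonise patient keys across sources through an
   explicit identifier-equivalence map (deterministic record linkage).
4. ``row_append`` — concatenate the per-source FHIR-shaped tables into a
   unified data mart under the canonical column order, keeping per-row
   provenance.
5. ``emit_fhir_resources`` — nest each mart row into a FHIR JSON resource
   instance; ``flatten_resource`` is its exact inverse.

FHIR-shaped column names carry a ``FHIR.`` prefix (``FHIR.Observation.value``),
matching how annotated/re-mapped tables are conventionally labelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import source_registry, timefmt
from .graph_store import KnowledgeGraph
from .query_engine import ResultTable
from .source_registry import MappingSpec, TransformSpec

#: display rendering for datetime-valued FHIR columns in tables and CSV output
DISPLAY_DATETIME_FORMAT = "%d/%m/%Y %H:%M"

#: canonical leading column order of the unified mart (relative paths);
#: any further columns follow lexically
CANONICAL_ORDER = ["subject.reference", "issued", "value", "Unit", "coding.code"]


class IntegrationError(ValueError):
    pass


def fhir_column(fhir_path: str) -> str:
    return f"FHIR.{fhir_path}"


@dataclass
class AnnotatedTable:
    source_id: str
    columns: list[str]
    rows: list[tuple]
    column_entities: list[str | None] | None = None


@dataclass
class FhirTable:
    source_id: str
    resource_type: str
    columns: list[str]  # all FHIR.<path> names
    rows: list[tuple]

    def column(self, name: str) -> list:
        return [row[self.columns.index(name)] for row in self.rows]


@dataclass
class UnifiedMart:
    resource_type: str
    columns: list[str]
    rows: list[tuple]
    provenance: list[str]  # source_id per row

    def to_csv(self, include_provenance: bool = False) -> str:
        header = list(self.columns) + (["_source"] if include_provenance else [])
        lines = [",".join(header)]
        for row, src in zip(self.rows, self.provenance):
            cells = ["" if v is None else str(v) for v in row]
            if include_provenance:
                cells.append(src)
            lines.append(",".join(cells))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def annotate_static(result: ResultTable, mappings: Sequence[MappingSpec]) -> AnnotatedTable:
    """Append one constant-valued column per STATIC mapping of this source."""
    statics = sorted(
        (m for m in mappings if m.kind == "STATIC" and m.source_id == result.source_id),
        key=lambda m: m.fhir_path,
    )
    columns = list(result.columns)
    constants = []
    for spec in statics:
        name = fhir_column(spec.fhir_path)
        if name in columns:
            raise IntegrationError(f"static column {name!r} collides with an existing column")
        columns.append(name)
        constants.append(spec.static_value)
    rows = [tuple(row) + tuple(constants) for row in result.rows]
    entities = None
    if result.column_entities is not None:
        entities = list(result.column_entities) + [None] * len(statics)
    return AnnotatedTable(result.source_id, columns, rows, entities)


def apply_transform(value, spec: TransformSpec):
    """Apply one transformation function to a scalar value."""
    if value is None or value == "":
        return value
    if spec.kind == "linear_unit":
        factor = float(spec.params["factor"])
        offset = float(spec.params.get("offset", 0.0))
        out = float(value) * factor + offset
        return int(out) if out == int(out) else out
    # datetime_reformat
    return timefmt.reformat(
        str(value), spec.params["source_format"], spec.params["target_format"]
    )


def inverse_transform(spec: TransformSpec) -> TransformSpec:
    """The declared inverse of an invertible transform."""
    if spec.kind == "linear_unit":
        factor = float(spec.params["factor"])
        offset = float(spec.params.get("offset", 0.0))
        return TransformSpec(
            spec.transform_id + ".inv",
            "linear_unit",
            {"factor": 1.0 / factor, "offset": -offset / factor},
        )
    return TransformSpec(
        spec.transform_id + ".inv",
        "datetime_reformat",
        {
            "source_format": spec.params["target_format"],
            "target_format": spec.params["source_format"],
        },
    )


def _coerce(value, value_type: str):
    if value is None or value == "":
        return None
    try:
        if value_type in {"integer", "int"}:
            return int(value)
        if value_type in {"float", "decimal", "real", "numeric"}:
            f = float(value)
            return int(f) if f == int(f) else f
    except (TypeError, ValueError) as exc:
        raise IntegrationError(f"value {value!r} cannot be cast to {value_type}") from exc
    return value


def remap_to_fhir(
    table: AnnotatedTable, mappings: Sequence[MappingSpec], graph: KnowledgeGraph
) -> FhirTable:
    """Rename mapped columns to FHIR paths, transform en route, drop the rest.

    Static (already FHIR-named) columns pass through.  Two local columns
    mapping to the same FHIR path within one source is ambiguous and
    rejected; a local column mapped to two FHIR paths likewise.
    """
    local = [
        m for m in mappings
        if m.source_id == table.source_id and m.local_ref is not None
    ]

    out_columns: list[str] = []
    plans: list[tuple[int, MappingSpec | None]] = []  # (source column index, mapping)
    seen_paths: dict[str, str] = {}
    dropped = []
    for idx, name in enumerate(table.columns):
        if name.startswith("FHIR."):
            out_columns.append(name)
            plans.append((idx, None))
            continue
        entity = table.column_entities[idx] if table.column_entities else None
        specs = [
            m for m in local
            if m.local_ref[2] == name and (entity is None or m.local_ref[1] == entity)
        ]
        if not specs:
            dropped.append(name)
            continue
        paths = sorted({s.fhir_path for s in specs})
        if len(paths) > 1:
            raise IntegrationError(
                f"column {name!r} maps to multiple FHIR paths: {paths}"
            )
        spec = specs[0]
        target = fhir_column(spec.fhir_path)
        if spec.fhir_path in seen_paths:
            raise IntegrationError(
                f"columns {seen_paths[spec.fhir_path]!r} and {name!r} both map to {spec.fhir_path}"
            )
        if target in out_columns:
            raise IntegrationError(f"column {name!r} collides with static {target!r}")
        seen_paths[spec.fhir_path] = name
        out_columns.append(target)
        plans.append((idx, spec))
    if dropped and not out_columns:
        warnings.warn(f"all columns of {table.source_id} are unmapped and were disregarded")

    resource_types = {c.split(".")[1] for c in out_columns}
    if len(resource_types) > 1:
        raise IntegrationError(f"mixed resource types in one table: {sorted(resource_types)}")
    resource_type = resource_types.pop() if resource_types else ""

    rows = []
    for row in table.rows:
        out_row = []
        for idx, spec in plans:
            value = row[idx]
            if spec is not None:
                node = source_registry.local_property_node(graph, *spec.local_ref)
                if spec.kind == "TRANSFORM":
                    value = apply_transform(
                        value, source_registry.get_transform(graph, spec.transform_id)
                    )
                fmt = node.get("datetime_format")
                if fmt and value not in (None, ""):
                    value = timefmt.reformat(str(value), fmt, DISPLAY_DATETIME_FORMAT)
                else:
                    value = _coerce(value, node.get("value_type", "string"))
            out_row.append(value)
        rows.append(tuple(out_row))
    return FhirTable(table.source_id, resource_type, out_columns, rows)


def link_records(
    tables: Sequence[FhirTable],
    key_path: str,
    equivalence: Mapping | None = None,
) -> list[FhirTable]:
    """Assign one canonical key to rows referring to the same subject.

    ``equivalence`` maps raw key values to canonical ones (identity by
    default); no rows are dropped or merged — linkage is purely a key
    harmonisation so the row-append stage can be grouped per subject.
    """
    equivalence = equivalence or {}
    key_col = fhir_column(key_path)
    out = []
    for table in tables:
        if key_col not in table.columns:
            raise IntegrationError(f"{table.source_id}: key column {key_col!r} missing")
        idx = table.columns.index(key_col)
        rows = []
        for row in table.rows:
            raw = row[idx]
            canonical = equivalence.get(raw, equivalence.get(str(raw), raw))
            rows.append(row[:idx] + (canonical,) + row[idx + 1 :])
        out.append(FhirTable(table.source_id, table.resource_type, list(table.columns), rows))
    return out


def canonical_columns(all_columns: set[str], resource_type: str) -> list[str]:
    lead = [
        fhir_column(f"{resource_type}.{rel}")
        for rel in CANONICAL_ORDER
        if fhir_column(f"{resource_type}.{rel}") in all_columns
    ]
    rest = sorted(c for c in all_columns if c not in lead)
    return lead + rest


def row_append(
    tables: Sequence[FhirTable],
    display_datetime_format: str = DISPLAY_DATETIME_FORMAT,
) -> UnifiedMart:
    """Concatenate per-source FHIR tables into the unified data mart.

    The mart schema is the union of the tables' columns in canonical order;
    values absent from a source are explicit nulls.  Rows are ordered by the
    issued timestamp then source id; the row count is conserved exactly.
    """
    if not tables:
        raise IntegrationError("row_append requires at least one table")
    resource_types = {t.resource_type for t in tables}
    if len(resource_types) != 1:
        raise IntegrationError(f"resource_type mismatch across tables: {sorted(resource_types)}")
    resource_type = resource_types.pop()
    all_columns = {c for t in tables for c in t.columns}
    columns = canonical_columns(all_columns, resource_type)
    issued_col = fhir_column(f"{resource_type}.issued")

    tagged: list[tuple[tuple, str]] = []
    for table in tables:
        index = {c: table.columns.index(c) for c in table.columns}
        for row in table.rows:
            out_row = tuple(
                row[index[c]] if c in index else None for c in columns
            )
            tagged.append((out_row, table.source_id))

    def sort_key(item):
        row, source_id = item
        if issued_col in columns:
            raw = row[columns.index(issued_col)]
            if raw not in (None, ""):
                try:
                    return (0, timefmt.parse_datetime(str(raw), display_datetime_format), source_id)
                except timefmt.DatetimeParseError:
                    pass
        return (1, str(row), source_id)

    tagged.sort(key=sort_key)
    return UnifiedMart(
        resource_type=resource_type,
        columns=columns,
        rows=[row for row, _ in tagged],
        provenance=[src for _, src in tagged],
    )


# ---------------------------------------------------------------------------
# FHIR resource instance emission


def emit_fhir_resources(mart: UnifiedMart) -> list[dict]:
    """One FHIR JSON resource instance per mart row.

    Dotted paths nest into objects; null cells are omitted keys.  A path that
    needs to be both a scalar and an object is a nesting conflict and is
    rejected.
    """
    instances = []
    rel_paths = [c.split(".", 2)[2] for c in mart.columns]  # strip "FHIR.<Resource>."
    for row in mart.rows:
        instance: dict = {"resourceType": mart.resource_type}
        for rel, value in zip(rel_paths, row):
            if value is None or value == "":
                continue
            node = instance
            segments = rel.split(".")
            for segment in segments[:-1]:
                nxt = node.setdefault(segment, {})
                if not isinstance(nxt, dict):
                    raise IntegrationError(f"path nesting conflict at {segment!r} in {rel!r}")
                node = nxt
            leaf = segments[-1]
            if isinstance(node.get(leaf), dict):
                raise IntegrationError(f"path nesting conflict at {leaf!r} in {rel!r}")
            node[leaf] = value
        instances.append(instance)
    return instances


def flatten_resource(instance: Mapping, columns: Sequence[str]) -> tuple:
    """Inverse of emission: project a resource instance onto mart columns."""
    def dig(node, segments):
        for segment in segments:
            if not isinstance(node, Mapping) or segment not in node:
                return None
            node = node[segment]
        return None if isinstance(node, Mapping) else node

    row = []
    for col in columns:
        rel = col.split(".", 2)[2]
        row.append(dig(instance, rel.split(".")))
    return tuple(row)
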