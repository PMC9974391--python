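"""Ostensive provenance: which local data back a FHIR attribute, and where
sources disagree.

``reverse_lookup`` walks the mapping graph backwards from a FHIR path to the
(source, table, column) triples that feed it.  ``trace_value`` goes one step
further and fetches the stored values for one subject from each backing
location — the ostensive example.  ``detect_value_conflicts`` compares those
values (datetimes at minute precision under their declared formats) and
raises an alert per disagreeing pair; ``resolve_primary`` applies a
configured primary/priority order to pick one value while keeping the
discarded alternatives visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import fhir_schema, source_registry, timefmt
from .graph_store import KnowledgeGraph
from .query_engine import Engine, SqliteConnector
from .source_registry import ConflictAlert, mapping_spec_of


class ProvenanceError(ValueError):
    pass


@dataclass(frozen=True)
class ProvenanceRecord:
    fhir_path: str
    source_id: str
    entity_name: str | None
    property_name: str | None
    mapping_id: str
    mapping_kind: str

    @property
    def ref(self) -> str:
        return f"{self.source_id}.{self.entity_name}.{self.property_name}"


@dataclass(frozen=True)
class PrimaryDesignation:
    fhir_path: str
    source_id: str
    tie_break_order: tuple[str, ...] = ()  # "source.entity.property" refs, highest priority first


@dataclass
class TracedValue:
    record: ProvenanceRecord
    values: list  # stored values for the subject (possibly empty / nulls)

    def non_null(self) -> list:
        return [v for v in self.values if v not in (None, "")]


@dataclass
class Resolution:
    value: object
    record: ProvenanceRecord
    discarded: list[TracedValue] = field(default_factory=list)


def reverse_lookup(fhir_path: str, graph: KnowledgeGraph) -> list[ProvenanceRecord]:
    """All mappings attached to a FHIR path, expanded to (src, tab, prop)."""
    fhir_schema.resolve_path(graph, fhir_path)
    records = []
    for node in graph.find_nodes("Mapping", {"fhir_path": fhir_path}):
        spec = mapping_spec_of(node)
        records.append(
            ProvenanceRecord(
                fhir_path=fhir_path,
                source_id=spec.source_id,
                entity_name=spec.local_ref[1] if spec.local_ref else None,
                property_name=spec.local_ref[2] if spec.local_ref else None,
                mapping_id=spec.mapping_id,
                mapping_kind=spec.kind,
            )
        )
    records.sort(key=lambda r: (r.source_id, r.entity_name or "", r.property_name or ""))
    return records


def _subject_key_column(
    engine: Engine, source_id: str, entity: str, resource_type: str
) -> str | None:
    """The local column of ``entity`` that carries the subject key, found via
    the source's mapping of the resource's subject-key path."""
    key_rel = engine.subject_key_paths.get(resource_type, "id")
    key_path = f"{resource_type}.{key_rel}"
    for node in engine.graph.find_nodes("Mapping", {"fhir_path": key_path}):
        spec = mapping_spec_of(node)
        if spec.local_ref and spec.local_ref[0] == source_id and spec.local_ref[1] == entity:
            return spec.local_ref[2]
    return None


def trace_value(
    fhir_path: str, subject_key, engine: Engine
) -> list[TracedValue]:
    """Fetch the stored values behind a FHIR path for one subject, per mapping.

    STATIC mappings trace to their constant.  For DIRECT/TRANSFORM mappings a
    per-source lookup runs against the backing entity, filtered on the
    entity's subject-key column.  A subject present in no source is an error;
    a subject whose backing columns are null still yields its records (with
    empty value lists) — the provenance is real even when the value is absent.
    """
    records = reverse_lookup(fhir_path, engine.graph)
    if not records:
        return []
    resource_type = fhir_path.split(".")[0]
    traced = []
    subject_seen = False
    for record in records:
        if record.mapping_kind == "STATIC":
            node = engine.graph.find_nodes("Mapping", {"mapping_id": record.mapping_id})[0]
            traced.append(TracedValue(record, [node.get("static_value")]))
            subject_seen = True
            continue
        key_col = _subject_key_column(engine, record.source_id, record.entity_name, resource_type)
        if key_col is None:
            raise ProvenanceError(
                f"no subject-key mapping for {record.source_id}.{record.entity_name}"
            )
        connector = engine.connector_for(record.source_id)
        if isinstance(connector, SqliteConnector):
            sql = (
                f"SELECT {record.property_name} FROM {record.entity_name} "
                f"WHERE {key_col} = {_sql_literal(subject_key)} ORDER BY {record.property_name}"
            )
            _, rows = connector.run(sql)
            values = [r[0] for r in rows]
        else:
            _, rows = connector.scan([record.property_name], [(key_col, subject_key)])
            values = sorted(r[0] for r in rows)
        if rows:
            subject_seen = True
        traced.append(TracedValue(record, values))
    if not subject_seen:
        raise ProvenanceError(f"subject {subject_key!r} not found in any source backing {fhir_path}")
    return traced


def _sql_literal(value) -> str:
    if isinstance(value, str):
        return "'" + value.replace("'", "''") + "'"
    return str(value)


def normalise_value(value, graph: KnowledgeGraph, record: ProvenanceRecord):
    """Comparison form of a traced value: datetimes to ISO-8601 at minute
    precision via the column's declared format; everything else to text."""
    if value in (None, ""):
        return None
    if record.entity_name is not None:
        node = source_registry.local_property_node(
            graph, record.source_id, record.entity_name, record.property_name
        )
        fmt = node.get("datetime_format")
        if fmt:
            return timefmt.to_iso_minute(str(value), fmt)
    return str(value)


def detect_value_conflicts(
    fhir_path: str,
    subject_key,
    engine: Engine,
    traced: Sequence[TracedValue] | None = None,
) -> list[ConflictAlert]:
    """One value_mismatch alert per pair of backing locations whose
    normalised values for the subject differ."""
    if traced is None:
        traced = trace_value(fhir_path, subject_key, engine)
    normalised: list[tuple[ProvenanceRecord, object, object]] = []
    for tv in traced:
        for value in tv.non_null():
            normalised.append(
                (tv.record, normalise_value(value, engine.graph, tv.record), value)
            )
    alerts = []
    for i in range(len(normalised)):
        for j in range(i + 1, len(normalised)):
            rec_a, norm_a, raw_a = normalised[i]
            rec_b, norm_b, raw_b = normalised[j]
            if rec_a.ref == rec_b.ref:
                continue
            if norm_a != norm_b:
                alerts.append(
                    ConflictAlert(
                        kind="value_mismatch",
                        fhir_path=fhir_path,
                        details=(
                            (rec_a.source_id, rec_a.entity_name, rec_a.property_name, raw_a),
                            (rec_b.source_id, rec_b.entity_name, rec_b.property_name, raw_b),
                        ),
                        subject_key=subject_key,
                    )
                )
    return alerts


def resolve_primary(
    fhir_path: str,
    traced: Sequence[TracedValue],
    designations: Mapping[str, PrimaryDesignation],
) -> Resolution:
    """Pick the authoritative value under the primary-source designation.

    The designated primary's value wins when non-null; otherwise the first
    non-null value along ``tie_break_order``.  Without a designation the
    fallback order is the deterministic record order (source, entity,
    property).  All-null traces are an error — there is nothing to resolve.
    """
    designation = designations.get(fhir_path)
    ordered: list[TracedValue] = []
    if designation is not None:
        by_ref = {tv.record.ref: tv for tv in traced}
        for ref in designation.tie_break_order:
            if ref in by_ref:
                ordered.append(by_ref[ref])
        for tv in traced:  # anything not named in the order comes after, in record order
            if tv not in ordered:
                ordered.append(tv)
        primary_first = [tv for tv in ordered if tv.record.source_id == designation.source_id]
        rest = [tv for tv in ordered if tv.record.source_id != designation.source_id]
        ordered = primary_first + rest
    else:
        ordered = sorted(
            traced, key=lambda tv: (tv.record.source_id, tv.record.entity_name or "",
                                    tv.record.property_name or "")
        )
    for tv in ordered:
        values = tv.non_null()
        if values:
            return Resolution(
                value=values[0],
                record=tv.record,
                discarded=[o for o in ordered if o is not tv and o.non_null()],
            )
    raise ProvenanceError(f"all traced values for {fhir_path} are null")
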