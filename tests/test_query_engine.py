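"""Query parsing, mapping discovery, planning, SQL rendering and execution."""

import itertools
import random
import sqlite3

import pytest

from fhirkg import fixtures
from fhirkg.query_engine import (
    FhirQuery,
    QueryError,
    QueryPlan,
    SourceExcluded,
    SqliteConnector,
    discover_mappings,
    execute_plan,
    hits_by_source,
    parse_fhir_query,
    plan_source_query,
    render_fhir_query,
    render_relational_query,
    run_federated_query,
)
from fhirkg.source_registry import (
    LocalPropertyDef,
    MappingSpec,
    SourceDescriptor,
    declare_flat_schema,
    register_source,
)

GLUCOSE = (
    "SELECT subject.reference, issued, value, Unit, coding.code "
    "FROM Observation WHERE coding.code = '2339-0' AND subject.reference = 1"
)


class TestParse:
    def test_glucose_query_has_two_filters(self, demo_engine):
        query = parse_fhir_query(GLUCOSE, demo_engine.graph)
        assert query.resource_type == "Observation"
        assert len(query.filters) == 2
        assert ("coding.code", "=", "2339-0") in query.filters
        assert ("subject.reference", "=", 1) in query.filters

    def test_query_without_filters_is_valid(self, demo_engine):
        query = parse_fhir_query("SELECT value FROM Observation", demo_engine.graph)
        assert query.filters == ()

    def test_unresolvable_path_named(self, demo_engine):
        with pytest.raises(Exception, match="bogus"):
            parse_fhir_query("SELECT bogus FROM Observation", demo_engine.graph)

    def test_parse_render_parse_is_fixpoint(self, demo_engine):
        query = parse_fhir_query(GLUCOSE, demo_engine.graph)
        assert parse_fhir_query(render_fhir_query(query), demo_engine.graph) == query

    def test_structured_form_equivalent_to_surface_form(self, demo_engine):
        structured = parse_fhir_query(
            {
                "resource_type": "Observation",
                "select": ["subject.reference", "issued", "value", "Unit", "coding.code"],
                "filters": [("coding.code", "=", "2339-0"), ("subject.reference", "=", 1)],
            },
            demo_engine.graph,
        )
        assert structured == parse_fhir_query(GLUCOSE, demo_engine.graph)


class TestDiscovery:
    def test_glucose_query_hits_both_sources(self, demo_engine):
        query = parse_fhir_query(GLUCOSE, demo_engine.graph)
        hits = discover_mappings(query, demo_engine.graph)
        assert set(hits_by_source(hits)) == {"mimic", "diabetes"}

    def test_path_with_no_mapping_errors(self, demo_engine):
        query = parse_fhir_query("SELECT status FROM Observation", demo_engine.graph)
        with pytest.raises(QueryError, match="Observation.status"):
            discover_mappings(query, demo_engine.graph)

    def test_hit_set_matches_full_scan_oracle(self, demo_engine):
        from fhirkg.source_registry import all_mappings, mapping_spec_of

        query = parse_fhir_query(GLUCOSE, demo_engine.graph)
        hits = discover_mappings(query, demo_engine.graph)
        paths = {query.full_path(p) for p in query.select} | {
            query.full_path(f[0]) for f in query.filters
        }
        expected = set()
        for node in all_mappings(demo_engine.graph):
            spec = mapping_spec_of(node)
            if spec.fhir_path not in paths:
                continue
            ok = all(
                str(query.filter_literal(cp)) == str(cv) for cp, cv in spec.context
            )
            if ok:
                expected.add(spec.mapping_id)
        assert {h.mapping.mapping_id for h in hits} == expected

    def test_context_mismatch_excludes_mapping(self, demo_engine):
        """Diabetes mappings are contextual on the glucose code; a potassium
        query must not discover them."""
        query = parse_fhir_query(
            "SELECT subject.reference, value FROM Observation "
            "WHERE coding.code = '2823-3' AND subject.reference = 1",
            demo_engine.graph,
        )
        hits = discover_mappings(query, demo_engine.graph)
        assert set(hits_by_source(hits)) == {"mimic"}


class TestPlanning:
    def _plans(self, engine, text):
        query = parse_fhir_query(text, engine.graph)
        plans = {}
        for sid, hits in hits_by_source(discover_mappings(query, engine.graph)).items():
            try:
                plans[sid] = plan_source_query(hits, engine.graph, query)
            except SourceExcluded:
                pass
        return query, plans

    def test_mimic_plan_joins_labevents_to_labitems(self, demo_engine):
        _, plans = self._plans(demo_engine, GLUCOSE)
        plan = plans["mimic"]
        assert plan.entities == ["LABEVENTS", "D_LABITEMS"]
        assert len(plan.join_conditions) == 1

    def test_minimal_join_set_matches_spanning_oracle(self, demo_engine):
        """The plan's join count equals entities-1 (a tree), and every pair of
        plan entities is connected inside the plan's own join set."""
        _, plans = self._plans(demo_engine, GLUCOSE)
        for plan in plans.values():
            if plan.source_kind != "relational":
                continue
            assert len(plan.join_conditions) == len(plan.entities) - 1
            adjacency = {e: set() for e in plan.entities}
            for join in plan.join_conditions:
                adjacency[join.left[0]].add(join.right[0])
                adjacency[join.right[0]].add(join.left[0])
            seen = {plan.entities[0]}
            stack = [plan.entities[0]]
            while stack:
                for nxt in adjacency[stack.pop()]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            assert seen == set(plan.entities)

    def test_flat_file_plan_has_no_joins(self, demo_engine):
        _, plans = self._plans(demo_engine, GLUCOSE)
        assert plans["diabetes"].join_conditions == []
        assert plans["diabetes"].entities == ["DIABETES"]

    def test_static_bindings_are_not_selections(self, demo_engine):
        _, plans = self._plans(demo_engine, GLUCOSE)
        bound = {p for p, _ in plans["diabetes"].static_bindings}
        assert "Observation.coding.code" in bound
        selected = {path for _, _, path in plans["diabetes"].selections}
        assert selected.isdisjoint(bound)

    def test_contradicted_static_excludes_source(self, demo_engine):
        """A STATIC subject satisfies a subject filter iff the literal matches."""
        _, plans = self._plans(
            demo_engine,
            "SELECT value, issued FROM Observation "
            "WHERE coding.code = '2339-0' AND subject.reference = 9",
        )
        assert "diabetes" not in plans
        assert "mimic" in plans

    def test_plan_determinism_byte_identical_sql(self, demo_engine):
        _, plans_a = self._plans(demo_engine, GLUCOSE)
        _, plans_b = self._plans(demo_engine, GLUCOSE)
        for sid in plans_a:
            assert render_relational_query(plans_a[sid]) == render_relational_query(plans_b[sid])


class TestContextualSource:
    def test_source_under_other_context_contributes_zero_plans(self, demo_engine, tmp_path):
        """A second flat-file source mapped under a different code must be
        excluded from glucose queries and included for its own code."""
        # build an independent engine so the session fixture stays pristine
        engine = fixtures.build_demo_engine(tmp_path)
        ctx = (("Observation.coding.code", "2823-3"),)
        potassium = tmp_path / "potassium.csv"
        potassium.write_text("WHEN,LEVEL\n21/10/2018 09:00,4.9\n")
        register_source(SourceDescriptor("homekit", "flat_file", str(potassium)), engine.graph)
        declare_flat_schema(
            "homekit",
            [
                LocalPropertyDef("homekit", "POTASSIUM", "WHEN", "string", "%d/%m/%Y %H:%M"),
                LocalPropertyDef("homekit", "POTASSIUM", "LEVEL", "float"),
            ],
            engine.graph,
        )
        from fhirkg.source_registry import add_mapping

        for spec in [
            MappingSpec("Observation.issued", "DIRECT", ("homekit", "POTASSIUM", "WHEN"), context=ctx),
            MappingSpec("Observation.value", "DIRECT", ("homekit", "POTASSIUM", "LEVEL"), context=ctx),
            MappingSpec("Observation.subject.reference", "STATIC", static_value=1,
                        source_id="homekit", context=ctx),
            MappingSpec("Observation.coding.code", "STATIC", static_value="2823-3",
                        source_id="homekit", context=ctx),
            MappingSpec("Observation.Unit", "STATIC", static_value="mEq/L",
                        source_id="homekit", context=ctx),
        ]:
            add_mapping(spec, engine.graph)
        from fhirkg.query_engine import CsvConnector

        engine.connectors["homekit"] = CsvConnector(str(potassium))

        glucose = run_federated_query(engine, GLUCOSE)
        assert "homekit" not in glucose.plans
        assert len(glucose.mart.rows) == 6

        potassium_q = (
            "SELECT subject.reference, issued, value, Unit, coding.code "
            "FROM Observation WHERE coding.code = '2823-3' AND subject.reference = 1"
        )
        res = run_federated_query(engine, potassium_q)
        assert set(res.plans) == {"mimic", "homekit"}
        idx = res.mart.columns.index("FHIR.Observation.value")
        assert {row[idx] for row in res.mart.rows} == {4.1, 4.9}


def make_random_mini_db(seed: int, path):
    """A random two/three-table database plus its declared plan."""
    rng = random.Random(seed)
    n_tables = rng.choice([2, 3])
    conn = sqlite3.connect(str(path))
    tables = {}
    for t in range(n_tables):
        name = f"T{t}"
        cols = ["K"] + [f"C{t}{i}" for i in range(rng.randint(1, 2))]
        conn.execute(f"CREATE TABLE {name} ({', '.join(c + ' INTEGER' for c in cols)})")
        rows = [
            tuple(rng.randint(0, 4) for _ in cols) for _ in range(rng.randint(0, 8))
        ]
        conn.executemany(
            f"INSERT INTO {name} VALUES ({','.join('?' * len(cols))})", rows
        )
        tables[name] = (cols, rows)
    conn.commit()
    conn.close()

    from fhirkg.source_registry import InternalJoin

    entities = list(tables)
    joins = [
        InternalJoin("mini", (entities[i], "K"), (entities[i + 1], "K"))
        for i in range(len(entities) - 1)
    ]
    filter_conditions = []
    if rng.random() < 0.7:
        ent = rng.choice(entities)
        col = rng.choice(tables[ent][0][1:])
        filter_conditions.append((ent, col, rng.randint(0, 4)))
    output_columns = []
    seen = set()
    for ent in entities:
        for col in tables[ent][0]:
            if col not in seen:
                seen.add(col)
                output_columns.append((ent, col))
    plan = QueryPlan(
        source_id="mini",
        source_kind="relational",
        entities=entities,
        join_conditions=joins,
        selections=[],
        filter_conditions=filter_conditions,
        static_bindings=[],
        output_columns=output_columns,
    )
    return tables, plan


def nested_loop_oracle(tables, plan):
    """Evaluate the plan by brute-force nested loops in memory."""
    entities = plan.entities
    col_index = {e: {c: i for i, c in enumerate(tables[e][0])} for e in entities}
    combos = itertools.product(*(tables[e][1] for e in entities))
    out = []
    for combo in combos:
        env = dict(zip(entities, combo))
        ok = all(
            env[j.left[0]][col_index[j.left[0]][j.left[1]]]
            == env[j.right[0]][col_index[j.right[0]][j.right[1]]]
            for j in plan.join_conditions
        )
        ok = ok and all(
            env[e][col_index[e][c]] == lit for e, c, lit in plan.filter_conditions
        )
        if ok:
            out.append(tuple(env[e][col_index[e][c]] for e, c in plan.output_columns))
    return sorted(out, key=lambda r: tuple(str(v) for v in r))


@pytest.mark.parametrize("seed", range(10))
def test_rendered_sql_matches_nested_loop_oracle(seed, tmp_path):
    db = tmp_path / f"mini{seed}.db"
    tables, plan = make_random_mini_db(seed, db)
    result = execute_plan(plan, SqliteConnector(db))
    assert result.rows == nested_loop_oracle(tables, plan)


class TestExecution:
    def test_mimic_glucose_plan_returns_four_rows(self, glucose_result):
        assert len(glucose_result.results["mimic"].rows) == 4

    def test_result_row_order_is_sorted(self, glucose_result):
        rows = glucose_result.results["mimic"].rows
        assert rows == sorted(rows, key=lambda r: tuple(str(v) for v in r))

    def test_plan_over_empty_selection_returns_zero_rows(self, demo_engine):
        query = parse_fhir_query(
            "SELECT value FROM Observation "
            "WHERE coding.code = '2339-0' AND subject.reference = 777",
            demo_engine.graph,
        )
        hits = hits_by_source(discover_mappings(query, demo_engine.graph))
        plan = plan_source_query(hits["mimic"], demo_engine.graph, query)
        result = execute_plan(plan, demo_engine.connector_for("mimic"))
        assert result.rows == []


class TestFederated:
    def test_glucose_unified_mart_has_six_rows(self, glucose_result):
        assert len(glucose_result.mart.rows) == 6

    def test_single_source_degeneracy(self, demo_engine):
        res = run_federated_query(
            demo_engine,
            "SELECT subject.reference, issued, value, Unit, coding.code "
            "FROM Observation WHERE coding.code = '2823-3' AND subject.reference = 1",
        )
        assert set(res.plans) == {"mimic"}
        assert len(res.mart.rows) == 1
        assert set(res.mart.provenance) == {"mimic"}

    def test_every_mart_value_traceable_to_source_row_or_static(self, glucose_result):
        """Completeness: each output row matches one source row or a STATIC binding."""
        mart = glucose_result.mart
        idx = {c: i for i, c in enumerate(mart.columns)}
        for row, src in zip(mart.rows, mart.provenance):
            table = glucose_result.fhir_tables[src]
            assert row in [
                tuple(
                    trow[table.columns.index(c)] if c in table.columns else None
                    for c in mart.columns
                )
                for trow in table.rows
            ]

    def test_stage_errors_carry_stage_name(self, demo_engine):
        from fhirkg.query_engine import StageError, Engine

        broken = Engine(
            graph=demo_engine.graph,
            connectors={"mimic": SqliteConnector("/nonexistent/nope.db"),
                        "diabetes": demo_engine.connectors["diabetes"]},
            subject_key_paths=demo_engine.subject_key_paths,
        )
        with pytest.raises(StageError, match=r"\[execute\]"):
            run_federated_query(broken, GLUCOSE)
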