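import pytest

from fhirkg import build_demo_engine
from fhirkg.fhir_schema import build_knowledge_graph, parse_resource_definitions
from fhirkg.fixtures import build_fhir_schema_fixture
from fhirkg.graph_store import KnowledgeGraph


@pytest.fixture(scope="session")
def demo_engine(tmp_path_factory):
    """The full case-study engine (read-only across tests)."""
    return build_demo_engine(tmp_path_factory.mktemp("demo"))


@pytest.fixture()
def fhir_graph():
    """A fresh graph holding only the parsed FHIR fixture schema."""
    graph = KnowledgeGraph()
    defs = parse_resource_definitions(build_fhir_schema_fixture())
    build_knowledge_graph(defs, graph)
    return graph


GLUCOSE_QUERY = (
    "SELECT subject.reference, issued, value, Unit, coding.code "
    "FROM Observation WHERE coding.code = '2339-0' AND subject.reference = 1"
)


@pytest.fixture(scope="session")
def glucose_result(demo_engine):
    from fhirkg.query_engine import parse_fhir_query, run_federated_query

    query = parse_fhir_query(GLUCOSE_QUERY, demo_engine.graph)
    return run_federated_query(demo_engine, query)
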