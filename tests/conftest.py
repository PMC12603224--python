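import json

import pytest

from metaphen.aggregation import build_profiles
from metaphen.ontology import load_mini_ontology, parse_ontology
from metaphen.synth import default_config, simulate_corpus


@pytest.fixture(scope="session")
def graph():
    return load_mini_ontology()


@pytest.fixture()
def four_term_graph():
    """Root A; B is-a A; C is-a B; D is-a B."""
    doc = {
        "nodes": [
            {"id": "T:A", "name": "A"},
            {"id": "T:B", "name": "B"},
            {"id": "T:C", "name": "C"},
            {"id": "T:D", "name": "D"},
        ],
        "edges": [
            {"child": "T:B", "parent": "T:A"},
            {"child": "T:C", "parent": "T:B"},
            {"child": "T:D", "parent": "T:B"},
        ],
    }
    return parse_ontology(json.dumps(doc), format="graph-json")


@pytest.fixture(scope="session")
def corpus_and_truth():
    """A moderate default-scale synthetic corpus shared across tests."""
    return simulate_corpus(default_config(seed=20240901, n_studies=80))


@pytest.fixture(scope="session")
def corpus(corpus_and_truth):
    return corpus_and_truth[0]


@pytest.fixture(scope="session")
def profiles(corpus, graph):
    return build_profiles(corpus, graph=graph)
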