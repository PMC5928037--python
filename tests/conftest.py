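"""Shared fixtures: small simulation configs and hand-built ontologies."""

import networkx as nx
import pytest

from degchar import GeneOntology, SimulationConfig


@pytest.fixture
def tiny_config():
    """Small but structurally complete simulation (fast unit-test scale)."""
    return SimulationConfig(
        seed=11,
        n_proteome=300,
        n_focal=103,
        go_n_terms=30,
        planted_terms=(("GO:0000010", 0.24, 0.08),),
    )


def build_ontology(edges, namespaces=None):
    """Ontology from (child, parent) pairs; default namespace for all terms."""
    g = nx.DiGraph()
    terms = {t for e in edges for t in e}
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    ns = namespaces or {t: "biological_process" for t in terms}
    return GeneOntology(g, {t: t for t in terms}, ns)
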