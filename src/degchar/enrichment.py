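"""GO overrepresentation with filtering and path-based redundancy reduction.

For every term, the focal set's observed annotation count is compared with
the count expected from the term's proteome frequency; the p-value is a
one-sided Fisher's exact test (over-representation) on the 2x2 table of
focal/non-focal x annotated/not-annotated.  Terms pass the filters when they
occur at least five times in the focal set, exceed 1.5-fold enrichment, and
reach p < 0.05.  Redundancy among passing terms is then reduced per path in
the ontology: along every maximal root-to-leaf path of the passing sub-DAG,
only the most frequent (highest focal count) term is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError

MIN_OBSERVED = 5
MIN_FOLD = 1.5  # strict: fold must exceed 1.5 (>150% of expected)
ALPHA = 0.05

NAMESPACE_ABBREV = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}


class GeneOntology:
    """An is_a DAG of GO terms (edges child -> parent) with namespaces."""

    def __init__(self, graph: nx.DiGraph, names: Mapping[str, str],
                 namespaces: Mapping[str, str]):
        if not nx.is_directed_acyclic_graph(graph):
            raise InputError("ontology graph must be acyclic")
        self.graph = graph
        self.names = dict(names)
        self.namespaces = dict(namespaces)
        self._ancestors: dict[str, frozenset[str]] = {}

    @classmethod
    def from_obo(cls, path: str | Path) -> "GeneOntology":
        multi = obonet.read_obo(str(path))
        graph = nx.DiGraph()
        names = {}
        namespaces = {}
        for term, data in multi.nodes(data=True):
            graph.add_node(term)
            names[term] = data.get("name", term)
            namespaces[term] = data.get("namespace", "")
        for child, parent, key in multi.edges(keys=True):
            if key == "is_a":
                graph.add_edge(child, parent)
        return cls(graph, names, namespaces)

    @classmethod
    def from_synthetic(cls, synthetic) -> "GeneOntology":
        return cls(synthetic.graph, synthetic.names, synthetic.namespaces)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` (excluding the term itself)."""
        if term not in self.graph:
            raise InputError(f"unknown term id {term}")
        cached = self._ancestors.get(term)
        if cached is None:
            # edges run child -> parent, so graph-descendants are ancestors
            cached = frozenset(nx.descendants(self.graph, term))
            self._ancestors[term] = cached
        return cached


@dataclass
class EnrichmentRecord:
    term: str
    name: str
    namespace: str
    observed: int  # focal proteins annotated (after propagation)
    proteome_count: int
    expected: float
    fold: float
    p: float
    passes_filters: Optional[bool] = None
    retained_after_reduction: Optional[bool] = None


def propagate_annotations(
    ontology: GeneOntology, direct: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """Apply the true-path rule: annotate each protein to all ancestors.

    Idempotent; unknown term ids are an input error.
    """
    full: dict[str, set[str]] = {}
    for protein, terms in direct.items():
        out: set[str] = set()
        for term in terms:
            out.add(term)
            out |= ontology.ancestors(term)
        full[protein] = out
    return full


def fisher_one_sided(observed: int, focal_n: int, proteome_count: int,
                     proteome_n: int) -> float:
    """One-sided (over-representation) Fisher's exact p.

    Equals the hypergeometric upper tail P(X >= observed) for X ~
    Hypergeom(N=proteome, K=annotated, n=focal).
    """
    return float(min(1.0, hypergeom.sf(observed - 1, proteome_n,
                                       proteome_count, focal_n)))


def term_enrichment(
    focal: set[str],
    annotations: Mapping[str, set[str]],
    term: str,
    ontology: Optional[GeneOntology] = None,
) -> EnrichmentRecord:
    """Observed/expected counts, fold enrichment and Fisher p for one term.

    ``annotations`` must be the propagated map over the whole proteome
    (unannotated proteins with empty sets); the focal set is a subset of the
    proteome.
    """
    if ontology is not None and term not in ontology:
        raise InputError(f"term {term} absent from the ontology")
    proteome_n = len(annotations)
    focal_n = len(focal)
    proteome_count = sum(1 for terms in annotations.values() if term in terms)
    observed = sum(1 for p in focal if term in annotations.get(p, ()))
    expected = focal_n * proteome_count / proteome_n if proteome_n else 0.0
    fold = observed / expected if expected > 0 else 0.0
    p = fisher_one_sided(observed, focal_n, proteome_count, proteome_n)
    name = ontology.names.get(term, term) if ontology is not None else term
    namespace = ontology.namespaces.get(term, "") if ontology is not None else ""
    return EnrichmentRecord(
        term=term, name=name, namespace=namespace,
        observed=observed, proteome_count=proteome_count,
        expected=expected, fold=fold, p=p,
    )


def filter_enriched(
    records: Sequence[EnrichmentRecord],
    min_observed: int = MIN_OBSERVED,
    min_fold: float = MIN_FOLD,
    alpha: float = ALPHA,
) -> list[EnrichmentRecord]:
    """Set ``passes_filters``: observed >= 5 AND fold > 1.5 AND p < 0.05."""
    for rec in records:
        rec.passes_filters = (
            rec.observed >= min_observed
            and rec.fold > min_fold
            and rec.p < alpha
        )
    return list(records)


def _nearest_passing_ancestors(
    ontology: GeneOntology, term: str, passing: set[str]
) -> set[str]:
    anc = ontology.ancestors(term) & passing
    if not anc:
        return set()
    # drop any passing ancestor that has another passing ancestor-of-term
    # strictly below it (i.e. keep only the minimal elements)
    dominated = set()
    for a in anc:
        dominated |= ontology.ancestors(a) & anc
    return anc - dominated


def reduce_by_path(
    ontology: GeneOntology, records: Sequence[EnrichmentRecord]
) -> list[EnrichmentRecord]:
    """Retain, per maximal path of the passing sub-DAG, the most frequent term.

    The sub-DAG links each passing term to its nearest passing ancestors.
    For every maximal root-to-leaf path, the term with the highest focal
    count wins (ties: smaller p, then lexicographically smaller id); the
    retained set is the union of the per-path winners.
    """
    by_term = {rec.term: rec for rec in records}
    passing = {rec.term for rec in records if rec.passes_filters}
    for rec in records:
        rec.retained_after_reduction = False
    if not passing:
        return list(records)

    sub = nx.DiGraph()  # edges parent -> child within the passing set
    sub.add_nodes_from(passing)
    for term in passing:
        for parent in _nearest_passing_ancestors(ontology, term, passing):
            sub.add_edge(parent, term)

    roots = [t for t in sub if sub.in_degree(t) == 0]
    leaves = [t for t in sub if sub.out_degree(t) == 0]

    def rank(term: str):
        rec = by_term[term]
        return (-rec.observed, rec.p, rec.term)

    retained: set[str] = set()
    for root in roots:
        for leaf in leaves:
            if root == leaf:
                paths: Iterable[list[str]] = [[root]] if not sub.out_degree(root) else []
            else:
                paths = nx.all_simple_paths(sub, root, leaf)
            for path in paths:
                retained.add(min(path, key=rank))
    for term in retained:
        by_term[term].retained_after_reduction = True
    return list(records)


def analyze_enrichment(
    ontology: GeneOntology,
    direct_annotations: Mapping[str, Iterable[str]],
    focal: set[str],
    min_observed: int = MIN_OBSERVED,
    min_fold: float = MIN_FOLD,
    alpha: float = ALPHA,
) -> list[EnrichmentRecord]:
    """Full per-namespace analysis: propagate, score all terms, filter, reduce."""
    annotations = propagate_annotations(ontology, direct_annotations)
    records = [
        term_enrichment(focal, annotations, term, ontology)
        for term in sorted(ontology.graph.nodes)
    ]
    filter_enriched(records, min_observed, min_fold, alpha)
    for namespace in sorted({r.namespace for r in records}):
        ns_records = [r for r in records if r.namespace == namespace]
        reduce_by_path(ontology, ns_records)
    return records


def read_gaf(path: str | Path) -> dict[str, set[str]]:
    """Accession -> direct term ids from a GAF 2.x file."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            direct.setdefault(cols[1], set()).add(cols[4])
    return direct


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabular view sorted by namespace then fold descending."""
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "namespace": NAMESPACE_ABBREV.get(r.namespace, r.namespace),
                "proteome_count": r.proteome_count,
                "observed": r.observed,
                "expected": r.expected,
                "fold": r.fold,
                "p": r.p,
                "passes_filters": r.passes_filters,
                "retained_after_reduction": r.retained_after_reduction,
            }
            for r in records
        ]
    )
    return df.sort_values(
        ["namespace", "fold"], ascending=[True, False]
    ).reset_index(drop=True)
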