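"""Phenotype-ontology semantic similarity and gene ranking.

Given a patient's set of HPO terms, every gene with ontology annotations
is scored in [0, 1] by semantic similarity between the query terms and
the gene's annotated terms.  The default measure is Lin similarity
combined by the symmetric best-match-average (BMA):

    lin(a, b) = 2 * IC(MICA(a, b)) / (IC(a) + IC(b))

where IC(t) = -ln(fraction of annotated genes annotated to t or any of
its descendants) and MICA is the common ancestor with maximal IC.  No
score threshold is applied: the whole ranked list is emitted and
downstream enrichment uses the full score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "OntologyIndex",
    "PhenotypeRanking",
    "build_ontology_index",
    "lin_similarity",
    "bma_similarity",
    "rank_genes_by_phenotype",
    "load_annotations",
]

import math


class OntologyError(ValueError):
    """Raised for malformed ontologies or annotation sets."""


@dataclass
class OntologyIndex:
    """Ontology DAG with annotation-frequency information content.

    ``parents`` holds is_a edges only.  ``ic`` is in nats; the root has
    IC 0 and IC never decreases from a term to its descendants.
    ``ancestors`` includes the term itself.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    ic: dict[str, float]
    root: str
    ancestors: dict[str, frozenset[str]]
    alt_ids: dict[str, str] = field(default_factory=dict)
    n_genes: int = 0

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id; error if unknown."""
        t = self.alt_ids.get(term, term)
        if t not in self.terms:
            raise OntologyError(f"term not in ontology: {term}")
        return t


@dataclass
class PhenotypeRanking:
    """Every annotated gene scored 0-1 against a query HPO term set."""

    query_terms: set[str]
    scores: dict[str, float]
    ordering: list[str]
    method: str = "lin_bma"

    @property
    def universe(self) -> set[str]:
        return set(self.scores)

    def rank_of(self, gene: str) -> int:
        return self.ordering.index(gene) + 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.ordering,
                "score": [self.scores[g] for g in self.ordering],
                "rank": range(1, len(self.ordering) + 1),
            }
        )


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a gene <tab> term TSV (HPOA-style extraction) into a dict."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            annotations.setdefault(gene, set()).add(term)
    return annotations


def _is_a_parents(graph: nx.MultiDiGraph | nx.DiGraph) -> dict[str, set[str]]:
    """Extract child -> is_a-parents from an obonet-style graph."""
    parents: dict[str, set[str]] = {n: set() for n in graph.nodes}
    multigraph = graph.is_multigraph()
    for edge in graph.edges(keys=True) if multigraph else graph.edges(data="relation"):
        child, parent, key = edge
        if multigraph:
            if key != "is_a":
                continue
        elif key not in (None, "is_a"):
            continue
        parents[child].add(parent)
    return parents


def build_ontology_index(
    obo: str | Path | nx.MultiDiGraph | nx.DiGraph,
    annotations: Mapping[str, Iterable[str]],
    unannotated_terms: str = "max_ic",
) -> OntologyIndex:
    """Parse the ontology and compute annotation-frequency IC.

    ``obo`` may be a path to an OBO file (parsed with obonet) or an
    already-loaded networkx graph in obonet's convention (edges point
    child -> parent).  IC uses ancestor propagation: a gene annotated to
    a term implicitly annotates all its ancestors.  Terms annotating no
    genes receive the maximum observed IC (``unannotated_terms="max_ic"``)
    or are dropped (``"exclude"``).
    """
    if isinstance(obo, (str, Path)):
        import obonet

        graph = obonet.read_obo(obo)
    else:
        graph = obo
    if not annotations:
        raise OntologyError("at least one annotated gene is required")

    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []) if isinstance(data, dict) else []:
            alt_ids[alt] = node

    parents = _is_a_parents(graph)
    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    dag.add_nodes_from(parents)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise OntologyError(f"ontology is_a graph contains a cycle: {cycle}")

    roots = [n for n, ps in parents.items() if not ps]
    if len(roots) != 1:
        raise OntologyError(f"expected a single root term, found {sorted(roots)}")
    root = roots[0]

    ancestors: dict[str, frozenset[str]] = {}
    # edges point child -> parent, so reverse topological order visits
    # parents before children
    for term in reversed(list(nx.topological_sort(dag))):
        anc = {term}
        for p in parents[term]:
            anc |= ancestors[p]
        ancestors[term] = frozenset(anc)

    terms = set(parents)
    bad = sorted(
        {t for ts in annotations.values() for t in ts if alt_ids.get(t, t) not in terms}
    )
    if bad:
        raise OntologyError(f"annotated terms absent from ontology: {bad[:10]}")
    for gene, ts in annotations.items():
        if not ts:
            raise OntologyError(f"gene {gene!r} has an empty annotation set")

    counts: dict[str, int] = {t: 0 for t in terms}
    for ts in annotations.values():
        covered: set[str] = set()
        for t in ts:
            covered |= ancestors[alt_ids.get(t, t)]
        for t in covered:
            counts[t] += 1
    n_genes = len(annotations)

    ic: dict[str, float] = {}
    for t in terms:
        if counts[t] > 0:
            ic[t] = -math.log(counts[t] / n_genes)
    if not ic:
        raise OntologyError("no term annotates any gene")
    max_ic = max(ic.values())
    zero_terms = [t for t in terms if counts[t] == 0]
    if unannotated_terms == "max_ic":
        for t in zero_terms:
            ic[t] = max_ic
    elif unannotated_terms == "exclude":
        terms = terms - set(zero_terms)
        ancestors = {t: a for t, a in ancestors.items() if t in terms}
    else:
        raise OntologyError(f"unknown unannotated_terms policy: {unannotated_terms!r}")

    return OntologyIndex(
        terms=terms,
        parents=parents,
        ic=ic,
        root=root,
        ancestors=ancestors,
        alt_ids=alt_ids,
        n_genes=n_genes,
    )


def _mica_ic(t1: str, t2: str, index: OntologyIndex) -> float:
    common = index.ancestors[t1] & index.ancestors[t2]
    if not common:
        return 0.0
    return max(index.ic[t] for t in common)


def lin_similarity(t1: str, t2: str, index: OntologyIndex) -> float:
    """Lin similarity of two terms; 0 when both terms carry no IC."""
    t1, t2 = index.resolve(t1), index.resolve(t2)
    denom = index.ic[t1] + index.ic[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * _mica_ic(t1, t2, index) / denom


def _best_match_avg(a: Iterable[str], b: list[str], index: OntologyIndex, cache: dict) -> float:
    total = 0.0
    n = 0
    for t in a:
        best = 0.0
        for u in b:
            key = (t, u) if t <= u else (u, t)
            s = cache.get(key)
            if s is None:
                s = lin_similarity(t, u, index)
                cache[key] = s
            if s > best:
                best = s
        total += best
        n += 1
    return total / n


def bma_similarity(
    a: Iterable[str],
    b: Iterable[str],
    index: OntologyIndex,
    _cache: dict | None = None,
) -> float:
    """Symmetric best-match-average Lin similarity of two term sets."""
    a, b = list(a), list(b)
    if not a or not b:
        raise OntologyError("best-match-average requires non-empty term sets")
    cache = _cache if _cache is not None else {}
    return 0.5 * (_best_match_avg(a, b, index, cache) + _best_match_avg(b, a, index, cache))


def _resnik_product(
    query: list[str], gene_terms: list[str], index: OntologyIndex, ic_max: float, cache: dict
) -> float:
    """Product over query terms of the best-match Resnik IC, normalized
    to [0, 1] by the maximum observed IC.  Opt-in alternative scorer."""
    prod = 1.0
    for t in query:
        best = 0.0
        for u in gene_terms:
            key = ("R", t, u) if t <= u else ("R", u, t)
            s = cache.get(key)
            if s is None:
                s = _mica_ic(index.resolve(t), index.resolve(u), index) / ic_max
                cache[key] = s
            best = max(best, s)
        prod *= best
    return prod


def rank_genes_by_phenotype(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    index: OntologyIndex,
    method: str = "lin_bma",
) -> PhenotypeRanking:
    """Score every annotated gene against the query term set.

    ``method`` is ``"lin_bma"`` (default) or ``"resnik_product"``.
    Unknown query terms raise; nothing is silently dropped.  Ties are
    broken lexicographically by gene id.
    """
    query = [index.resolve(t) for t in query]
    if not query:
        raise OntologyError("query term set is empty")
    cache: dict = {}
    ic_max = max(index.ic.values())
    scores: dict[str, float] = {}
    for gene, terms in annotations.items():
        terms = [index.resolve(t) for t in terms]
        if method == "lin_bma":
            scores[gene] = bma_similarity(query, terms, index, _cache=cache)
        elif method == "resnik_product":
            scores[gene] = _resnik_product(query, terms, index, ic_max, cache)
        else:
            raise OntologyError(f"unknown similarity method: {method!r}")
    ordering = sorted(scores, key=lambda g: (-scores[g], g))
    return PhenotypeRanking(
        query_terms=set(query), scores=scores, ordering=ordering, method=method
    )
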