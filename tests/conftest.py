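import math

import networkx as nx
import numpy as np
import pytest

from evoranker.npp import BitscoreTable, CladeMap, normalize_bitscores
from evoranker.phenotype import build_ontology_index


@pytest.fixture
def toy_dag():
    """Root R with children A and D; B and C are children of A.

    Four annotated genes: gB {B}, gC {C}, gD1 {D}, gD2 {D}, so with
    ancestor propagation A annotates 2/4 genes (IC = ln 2) and B, C
    annotate 1/4 each (IC = ln 4).
    """
    g = nx.MultiDiGraph()
    for term in "RABCD":
        g.add_node(term, name=term)
    for child, parent in [("A", "R"), ("D", "R"), ("B", "A"), ("C", "A")]:
        g.add_edge(child, parent, key="is_a")
    annotations = {"gB": {"B"}, "gC": {"C"}, "gD1": {"D"}, "gD2": {"D"}}
    return g, annotations


@pytest.fixture
def toy_index(toy_dag):
    graph, annotations = toy_dag
    return build_ontology_index(graph, annotations), annotations


@pytest.fixture
def small_matrix():
    """10 genes x 9 species random bitscore table, 3 clades of 3 species."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(10)]
    species = [f"s{j}" for j in range(9)]
    best = 400.0 * np.exp2(np.minimum(0.0, -3.0 + rng.standard_normal((10, 9))))
    bt = BitscoreTable(genes=genes, species=species, best_hit=best,
                       self_hit=np.full(10, 400.0))
    clades = CladeMap({
        "CladeA": set(species[0:3]),
        "CladeB": set(species[3:6]),
        "CladeC": set(species[6:9]),
    })
    return normalize_bitscores(bt), clades
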