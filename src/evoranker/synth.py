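"""Synthetic fixtures with the statistical structure the method assumes.

Real inputs to the pipeline — a 1,028-genome conservation matrix,
patient exomes, the HPO with its gene annotations, a STRING network —
are large and partly access-restricted.  This module generates small
deterministic stand-ins that carry the structure the method exploits:

- a conservation matrix with planted co-evolving gene modules (a shared
  latent per-species factor giving a tunable within-module correlation
  ``rho``, optionally restricted to a subset of clades);
- a random rooted ontology DAG with gene annotations whose term
  frequencies span information contents from 0 up to ln(n_genes);
- spike-in "patients": an annotated variant table with one planted
  passing variant in a causal gene plus decoy candidates and rows
  engineered to fail each filter, and an HPO query drawn from the terms
  annotating the causal gene's module partners;
- a benchmark harness reporting the rank of the planted gene and
  aggregate top-k accuracies over many seeded scenarios.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .npp import (
    CANONICAL_CLADES,
    BitscoreTable,
    CladeMap,
    ConservationMatrix,
    NppError,
    normalize_bitscores,
)
from .variants import DEFAULT_COLUMN_MAP

__all__ = [
    "SyntheticScenario",
    "ScenarioCase",
    "default_clade_map",
    "gen_conservation_matrix",
    "gen_ontology_and_annotations",
    "write_obo",
    "gen_patient",
    "generate_case",
    "run_benchmark",
]


def default_clade_map(n_species: int, n_clades: int = 4) -> tuple[list[str], CladeMap]:
    """Evenly partition ``S###`` species into named clades + Eukaryota."""
    species = [f"S{i:03d}" for i in range(n_species)]
    names = list(CANONICAL_CLADES[:n_clades])
    bounds = np.linspace(0, n_species, n_clades + 1).astype(int)
    clades = {
        name: set(species[bounds[i]: bounds[i + 1]]) for i, name in enumerate(names)
    }
    clades["Eukaryota"] = set(species)
    return species, CladeMap(clades)


def gen_conservation_matrix(
    n_genes: int,
    n_species: int,
    clade_map: CladeMap | None = None,
    modules: Sequence[tuple[Iterable[str], float, Iterable[str] | None]] = (),
    seed: int = 0,
    genes: Sequence[str] | None = None,
    missing_rate: float = 0.02,
    restricted_presence: bool = False,
    self_hit: float = 400.0,
    mu: float = -4.0,
    sigma: float = 1.0,
) -> tuple[BitscoreTable, ConservationMatrix]:
    """Background-noise bitscore table with planted co-evolving modules.

    Each module is ``(gene_ids, rho, clades)``: within the listed clades
    (``None`` = everywhere) the module genes share a latent per-species
    factor so that any two of them correlate at ``rho``.  Log2 ratios
    are ``mu + sigma * z`` clipped at 0 (a hit never outscores the
    self-hit), converted back to bitscores.  With ``restricted_presence``
    module genes get no hits at all outside their module clades,
    emulating clade-restricted gene families.  Missing hits elsewhere
    are dropped at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(n_genes)]
    genes = list(genes)
    if len(genes) != n_genes:
        raise ValueError("gene list length does not match n_genes")
    if clade_map is None:
        species, clade_map = default_clade_map(n_species)
    else:
        species = sorted(clade_map["Eukaryota"])
        if len(species) != n_species:
            raise ValueError("clade map does not cover n_species species")
    gene_index = {g: i for i, g in enumerate(genes)}
    sp_index = {s: j for j, s in enumerate(species)}

    v = mu + sigma * rng.standard_normal((n_genes, n_species))
    presence_override = np.ones((n_genes, n_species), dtype=bool)
    seen: set[str] = set()
    for module_genes, rho, clades in modules:
        module_genes = list(module_genes)
        if len(module_genes) > n_genes:
            raise ValueError("module larger than the gene universe")
        if not (0.0 <= rho <= 1.0):
            raise ValueError(f"module rho out of [0, 1]: {rho}")
        overlap = seen & set(module_genes)
        if overlap:
            raise ValueError(f"modules are not disjoint: {sorted(overlap)[:5]}")
        seen |= set(module_genes)
        idx = np.array([gene_index[g] for g in module_genes])
        if clades is None:
            cols = np.arange(n_species)
        else:
            members: set[str] = set()
            for c in clades:
                members |= clade_map[c]
            cols = np.array(sorted(sp_index[s] for s in members if s in sp_index))
        factor = rng.standard_normal(len(cols))
        eps = rng.standard_normal((len(idx), len(cols)))
        v[np.ix_(idx, cols)] = mu + sigma * (
            math.sqrt(rho) * factor[None, :] + math.sqrt(1.0 - rho) * eps
        )
        if restricted_presence and clades is not None:
            outside = np.setdiff1d(np.arange(n_species), cols)
            presence_override[np.ix_(idx, outside)] = False

    v = np.minimum(v, 0.0)
    best = self_hit * np.exp2(v)
    if missing_rate > 0:
        drop = rng.random((n_genes, n_species)) < missing_rate
        # keep at least one observed hit per species column
        for j in range(n_species):
            if drop[:, j].all():
                drop[rng.integers(n_genes), j] = False
        best[drop] = np.nan
    best[~presence_override] = np.nan

    bt = BitscoreTable(
        genes=genes,
        species=species,
        best_hit=best,
        self_hit=np.full(n_genes, self_hit),
    )
    return bt, normalize_bitscores(bt)


def gen_ontology_and_annotations(
    n_terms: int = 60,
    depth: int = 4,
    n_genes: int = 240,
    seed: int = 0,
    genes: Sequence[str] | None = None,
    terms_per_gene: tuple[int, int] = (2, 4),
) -> tuple[nx.MultiDiGraph, dict[str, set[str]]]:
    """Random rooted is_a DAG plus gene annotations spanning the IC range.

    Terms are laid out in ``depth`` layers under a single root; each
    term has 1-2 parents in the layer above.  Genes draw a few terms
    uniformly from the non-root terms, and one designated leaf is
    annotated to exactly one gene so the realized ICs run from 0 (root)
    to ln(n_genes).
    """
    if n_terms < depth + 2:
        raise ValueError("need at least depth + 2 terms")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(n_genes)]
    genes = list(genes)

    root = "T:0000"
    term_ids = [f"T:{i:04d}" for i in range(1, n_terms)]
    weights = np.arange(1, depth + 1, dtype=float)  # deeper layers are wider
    sizes = np.maximum(1, (weights / weights.sum() * len(term_ids)).astype(int))
    while sizes.sum() < len(term_ids):
        sizes[-1] += 1
    while sizes.sum() > len(term_ids):
        sizes[np.argmax(sizes)] -= 1

    graph = nx.MultiDiGraph()
    graph.add_node(root, name="synthetic phenotype root")
    layers: list[list[str]] = [[root]]
    cursor = 0
    for size in sizes:
        layer = term_ids[cursor: cursor + size]
        cursor += size
        above = layers[-1]
        for term in layer:
            graph.add_node(term, name=f"synthetic term {term}")
            n_parents = 1 if len(above) == 1 else int(rng.integers(1, 3))
            parents = rng.choice(len(above), size=min(n_parents, len(above)), replace=False)
            for p in parents:
                graph.add_edge(term, above[p], key="is_a")
        layers.append(layer)

    annotatable = [t for t in term_ids[:-1]]  # last term reserved as the rare leaf
    rare_leaf = term_ids[-1]
    lo, hi = terms_per_gene
    annotations: dict[str, set[str]] = {}
    for gene in genes:
        n_t = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(annotatable), size=min(n_t, len(annotatable)), replace=False)
        annotations[gene] = {annotatable[i] for i in picks}
    annotations[genes[0]] = annotations[genes[0]] | {rare_leaf}
    return graph, annotations


def write_obo(graph: nx.MultiDiGraph, path: str | Path) -> None:
    """Serialize a synthetic ontology DAG to OBO 1.2 text."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for node in sorted(graph.nodes):
            fh.write(f"\n[Term]\nid: {node}\n")
            name = graph.nodes[node].get("name", node)
            fh.write(f"name: {name}\n")
            parents = sorted(
                p for _c, p, k in graph.out_edges(node, keys=True) if k == "is_a"
            )
            for p in parents:
                fh.write(f"is_a: {p}\n")


@dataclass
class SyntheticScenario:
    """One spike-in case: a planted causal gene inside a co-evolving,
    phenotype-annotated module, among decoy candidates.

    ``annotation_overlap`` is the fraction of module partners annotated
    with the patient's query terms (and linked to the causal gene in the
    interaction network); ``rho_within`` is the planted within-module
    correlation.  ``rho_within = 0`` with ``annotation_overlap = 0`` is
    the null configuration.
    """

    seed: int
    n_genes: int = 320
    n_species: int = 120
    n_clades: int = 4
    module_size: int = 10
    rho_within: float = 0.9
    clade_restriction: tuple[str, ...] | None = ("Chordata", "Ecdysozoa")
    n_decoys: int = 20
    annotation_overlap: float = 0.8
    n_annotated: int = 240
    n_terms: int = 60
    depth: int = 4
    n_query_terms: int = 4
    mode: str = "recessive"
    k: int = 10  # top co-evolved partners retrieved per clade
    background_degree: int = 8
    n_filter_fodder: int = 30  # extra variant rows built to fail the filters


@dataclass
class ScenarioCase:
    """Fully materialized inputs (and truth) for one scenario."""

    scenario: SyntheticScenario
    causal_gene: str
    module_genes: list[str]  # partners, causal excluded
    decoys: list[str]
    bitscores: BitscoreTable
    matrix: ConservationMatrix
    clade_map: CladeMap
    ontology: nx.MultiDiGraph
    annotations: dict[str, set[str]]
    network_edges: pd.DataFrame  # gene1, gene2, combined_score
    variants: pd.DataFrame
    hpo_query: list[str]

    @property
    def candidates(self) -> list[str]:
        return sorted([self.causal_gene, *self.decoys])


def gen_patient(
    causal_gene: str,
    decoy_genes: Sequence[str],
    rng: np.random.Generator,
    mode: str = "recessive",
    other_genes: Sequence[str] = (),
    n_filter_fodder: int = 30,
) -> pd.DataFrame:
    """ANNOVAR-style variant table with one planted passing variant.

    The causal gene and every decoy receive a rare, predicted-deleterious
    variant with the zygosity the mode requires; ``n_filter_fodder``
    additional rows are engineered to fail the class, frequency, or
    deleteriousness filter, in roughly equal parts.
    """
    zyg = "hom" if mode == "recessive" else "het"
    freq_hi = 0.02 if mode == "recessive" else 0.0005
    rows = []

    def row(gene, effect, zygosity, gnomad, revel, sift, spliceai=""):
        rows.append(
            {
                "Gene": gene,
                "Effect": effect,
                "Zygosity": zygosity,
                "gnomAD_AF": gnomad,
                "AF_popmax": gnomad,
                "InHouse_AF": gnomad,
                "dbscSNV_RF_SCORE": "",
                "dbscSNV_ADA_SCORE": "",
                "SpliceAI": spliceai,
                "Polyphen2_HDIV_score": "",
                "REVEL": revel,
                "SIFT_score": sift,
            }
        )

    row(causal_gene, "nonsynonymous", zyg, "", 0.95, 0.01)  # novel, deleterious
    for gene in decoy_genes:
        row(gene, "nonsynonymous", zyg, round(float(rng.uniform(0, freq_hi)), 6),
            round(float(rng.uniform(0.5, 1.0)), 3), round(float(rng.uniform(0, 0.5)), 3))

    pool = list(other_genes) if len(other_genes) else [f"X{i:03d}" for i in range(200)]
    for i in range(n_filter_fodder):
        gene = pool[int(rng.integers(len(pool)))]
        kind = i % 3
        if kind == 0:  # wrong class
            row(gene, rng.choice(["intronic", "UTR", "ncRNA"]), "het", 0.0001, "", "")
        elif kind == 1:  # too frequent
            row(gene, "nonsynonymous", "het", round(float(rng.uniform(0.05, 0.5)), 4),
                0.9, 0.01)
        else:  # predicted benign
            row(gene, "nonsynonymous", "het", 0.0001, 0.1, 0.95)
    df = pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP.values())[:-1])
    df["VariantID"] = [f"v{i:04d}" for i in range(len(df))]
    return df


def generate_case(scenario: SyntheticScenario) -> ScenarioCase:
    """Materialize every pipeline input for one scenario, deterministically."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = [f"G{i:04d}" for i in range(sc.n_genes)]

    picks = rng.choice(sc.n_genes, size=sc.module_size + sc.n_decoys, replace=False)
    module = [genes[i] for i in picks[: sc.module_size]]
    causal = module[0]
    partners = module[1:]
    decoys = [genes[i] for i in picks[sc.module_size:]]

    species, clade_map = default_clade_map(sc.n_species, sc.n_clades)
    bt, matrix = gen_conservation_matrix(
        sc.n_genes,
        sc.n_species,
        clade_map=clade_map,
        modules=[(module, sc.rho_within, sc.clade_restriction)],
        seed=int(rng.integers(2**31)),
        genes=genes,
        restricted_presence=sc.clade_restriction is not None,
    )

    # annotated universe: all module partners plus a random fill
    fill = [g for g in genes if g not in set(module)]
    fill_idx = rng.choice(len(fill), size=sc.n_annotated - len(partners), replace=False)
    universe = sorted(set(partners) | {fill[i] for i in fill_idx})
    ontology, annotations = gen_ontology_and_annotations(
        n_terms=sc.n_terms,
        depth=sc.depth,
        n_genes=len(universe),
        seed=int(rng.integers(2**31)),
        genes=universe,
    )

    # patient phenotype: deep-ish terms; the annotated fraction of the
    # module partners carries exactly these terms
    deep_terms = [t for t in sorted(ontology.nodes) if t not in ("T:0000",)][-(sc.n_terms // 2):]
    q_idx = rng.choice(len(deep_terms), size=sc.n_query_terms, replace=False)
    query = sorted(deep_terms[i] for i in q_idx)
    n_pheno = int(round(sc.annotation_overlap * len(partners)))
    pheno_idx = rng.choice(len(partners), size=n_pheno, replace=False)
    pheno_partners = [partners[i] for i in pheno_idx]
    for g in pheno_partners:
        annotations[g] = set(query)

    # interaction network: causal links to its phenotype-annotated
    # partners; every candidate gets background partners
    edges: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), score)

    for g in pheno_partners:
        add_edge(causal, g, round(float(rng.uniform(0.7, 0.99)), 3))
    for cand in [causal, *decoys]:
        n_bg = int(rng.integers(max(1, sc.background_degree - 3), sc.background_degree + 4))
        bg = rng.choice(len(universe), size=n_bg, replace=False)
        for i in bg:
            add_edge(cand, universe[i], round(float(rng.uniform(0.5, 0.95)), 3))
    for _ in range(sc.n_genes // 2):  # unrelated noise edges
        a, b = rng.choice(len(universe), size=2, replace=False)
        add_edge(universe[a], universe[b], round(float(rng.uniform(0.5, 0.95)), 3))
    network_edges = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["gene1", "gene2", "combined_score"],
    )

    variants = gen_patient(
        causal,
        decoys,
        rng,
        mode=sc.mode,
        other_genes=[g for g in genes if g not in set(module) | set(decoys)],
        n_filter_fodder=sc.n_filter_fodder,
    )
    return ScenarioCase(
        scenario=sc,
        causal_gene=causal,
        module_genes=partners,
        decoys=decoys,
        bitscores=bt,
        matrix=matrix,
        clade_map=clade_map,
        ontology=ontology,
        annotations=annotations,
        network_edges=network_edges,
        variants=variants,
        hpo_query=query,
    )


def run_benchmark(
    scenarios: Iterable[SyntheticScenario],
    combine_method: str = "fisher",
    min_overlap: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Run the full pipeline on each scenario and score top-k accuracy.

    Returns a per-scenario table (seed, mode, n_candidates, causal rank)
    and aggregate top-1/3/5/10 percentages, the benchmark metric used
    throughout: the share of cases where the planted gene ranks first
    (or within k) among the surviving candidates.
    """
    from .pipeline import run_case

    rows = []
    for sc in scenarios:
        case = generate_case(sc)
        result = run_case(case, combine_method=combine_method, min_overlap=min_overlap)
        rank = result.enrichment.rank_of(case.causal_gene)
        rows.append(
            {
                "seed": sc.seed,
                "mode": sc.mode,
                "rho_within": sc.rho_within,
                "annotation_overlap": sc.annotation_overlap,
                "n_candidates": len(result.candidates),
                "causal_rank": rank,
            }
        )
    table = pd.DataFrame(rows)
    summary = topk_summary(table["causal_rank"])
    return table, summary


def topk_summary(ranks: Iterable[int]) -> dict[str, float]:
    """Top-1/3/5/10 percentages from a list of causal-gene ranks."""
    ranks = np.asarray(list(ranks))
    summary = {
        f"top{k}_pct": float(100.0 * (ranks <= k).mean()) for k in (1, 3, 5, 10)
    }
    summary["n_scenarios"] = float(ranks.size)
    return summary
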