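"""End-to-end orchestration: inputs -> candidate ranking -> exports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import npp, phenotype
from .enrichment import EnrichmentResult, prioritize
from .interactions import InteractionNetwork, partners
from .npp import CladeMap, ConservationMatrix, CoevolutionResult, NppError
from .phenotype import OntologyIndex, PhenotypeRanking


@dataclass
class CaseResult:
    candidates: list[str]
    ranking: PhenotypeRanking
    coevolution: dict[str, CoevolutionResult | None]
    enrichment: EnrichmentResult


def prioritize_case(
    candidates: Sequence[str],
    hpo_terms: Sequence[str],
    matrix: ConservationMatrix,
    clade_map: CladeMap,
    index: OntologyIndex,
    annotations: Mapping[str, Iterable[str]],
    network: InteractionNetwork | None,
    k: int = 50,
    min_species: int | None = None,
    min_overlap: int = 3,
    combine_method: str = "fisher",
    similarity_method: str = "lin_bma",
) -> CaseResult:
    """Rank candidate genes for one patient.

    Computes the phenotype ranking of the annotated universe once, then
    per candidate the merged co-evolved partner set (skipping candidates
    absent from the matrix or without clade coverage) and the network
    partner set, and feeds both into the KS-enrichment combination.
    """
    ranking = phenotype.rank_genes_by_phenotype(
        hpo_terms, annotations, index, method=similarity_method
    )
    coevo: dict[str, CoevolutionResult | None] = {}
    for gene in candidates:
        if gene not in matrix:
            coevo[gene] = None
            continue
        try:
            coevo[gene] = npp.coevolution_profile(
                matrix, gene, clade_map, k=k, min_species=min_species
            )
        except NppError:
            coevo[gene] = None
    net_partners = {
        gene: (partners(network, gene) if network is not None else set())
        for gene in candidates
    }
    enrichment = prioritize(
        list(candidates),
        ranking,
        coevo,
        net_partners,
        combine_method=combine_method,
        min_overlap=min_overlap,
    )
    return CaseResult(
        candidates=list(candidates), ranking=ranking, coevolution=coevo,
        enrichment=enrichment,
    )


def run_case(case, combine_method: str = "fisher", min_overlap: int = 3) -> CaseResult:
    """Run a synthetic scenario end to end, variant filtering included."""
    import networkx as nx

    from .interactions import InteractionNetwork as _IN
    from .phenotype import build_ontology_index
    from .variants import filter_variants, records_from_frame

    sc = case.scenario
    records = records_from_frame(case.variants)
    candidates = sorted(filter_variants(records, sc.mode).genes)
    index = build_ontology_index(case.ontology, case.annotations)
    graph = nx.Graph()
    for _, row in case.network_edges.iterrows():
        graph.add_edge(row["gene1"], row["gene2"], score=float(row["combined_score"]))
    network = _IN(graph=graph, threshold=0.5)
    return prioritize_case(
        candidates,
        case.hpo_query,
        case.matrix,
        case.clade_map,
        index,
        case.annotations,
        network,
        k=sc.k,
        min_overlap=min_overlap,
        combine_method=combine_method,
    )


def export_subnetwork(
    candidate: str,
    coevo: CoevolutionResult | None,
    network: InteractionNetwork | None,
    ranking: PhenotypeRanking,
    top_n: int = 50,
) -> pd.DataFrame:
    """Cytoscape-loadable edge list around one candidate gene.

    Keeps the candidate's partners that fall within the top ``top_n``
    phenotype-ranked genes; co-evolution edges are labeled with the
    clade achieving the partner's best rank (weight = Pearson r at that
    clade), network edges with source ``STRING`` (weight = combined
    score).
    """
    keep = set(ranking.ordering[:top_n])
    rows = []
    if coevo is not None:
        best_r: dict[str, tuple[str, float]] = {}
        for clade, entries in coevo.per_clade.items():
            for gene, rank, r in entries:
                if gene in coevo.merged and coevo.merged[gene] == (rank, clade):
                    best_r[gene] = (clade, r)
        for gene, (clade, r) in sorted(best_r.items()):
            if gene in keep:
                rows.append((candidate, gene, clade, r))
    if network is not None:
        for gene in sorted(partners(network, candidate)):
            if gene in keep:
                rows.append((candidate, gene, "STRING", network.score(candidate, gene)))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "source", "weight"])
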