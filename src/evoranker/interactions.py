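"""Functional-interaction networks (STRING-style combined scores).

Interactions are undirected gene pairs with a combined confidence score
in [0, 1].  Files in the STRING links dialect carry integer scores on a
0-1000 scale; that dialect is auto-detected (any score above 1) and
rescaled.  The default confidence threshold of 0.5 corresponds to a
medium-confidence network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

__all__ = ["InteractionNetwork", "load_network", "load_aliases", "partners"]


class NetworkError(ValueError):
    pass


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def score(self, a: str, b: str) -> float | None:
        data = self.graph.get_edge_data(a, b)
        return None if data is None else data["score"]

    def edge_table(self):
        import pandas as pd

        rows = [
            (min(a, b), max(a, b), d["score"]) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(sorted(rows), columns=["gene1", "gene2", "combined_score"])


def load_aliases(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping network identifiers to gene symbols."""
    aliases: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident, symbol = line.split("\t")[:2]
            aliases[ident] = symbol
    return aliases


def load_network(
    path: str | Path,
    threshold: float = 0.5,
    aliases: Mapping[str, str] | str | Path | None = None,
) -> InteractionNetwork:
    """Load a (gene1, gene2, combined_score) TSV into a thresholded graph.

    Scores on the STRING 0-1000 integer dialect are detected (any score
    > 1) and divided by 1000.  Edges below ``threshold`` are dropped,
    duplicate edges are collapsed keeping the maximum score, self-edges
    are discarded.  Unmapped identifiers (when an alias table is given)
    drop the edge, with a count recorded in ``meta``.
    """
    if not (0.0 <= threshold <= 1.0):
        raise NetworkError(f"threshold out of [0, 1]: {threshold}")
    if aliases is not None and not isinstance(aliases, Mapping):
        aliases = load_aliases(aliases)

    raw_edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise NetworkError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_score = parts[0], parts[1], parts[2]
            if lineno == 1:
                try:
                    float(raw_score)
                except ValueError:
                    continue  # header row
            try:
                score = float(raw_score)
            except ValueError:
                raise NetworkError(f"line {lineno}: non-numeric score {raw_score!r}") from None
            raw_edges.append((a, b, score))

    string_dialect = any(s > 1.0 for _, _, s in raw_edges)
    n_unmapped = n_self = 0
    graph = nx.Graph()
    for a, b, score in raw_edges:
        if string_dialect:
            score /= 1000.0
        if not (0.0 <= score <= 1.0):
            raise NetworkError(f"score out of range after normalization: {score}")
        if aliases is not None:
            if a not in aliases or b not in aliases:
                n_unmapped += 1
                continue
            a, b = aliases[a], aliases[b]
        if a == b:
            n_self += 1
            continue
        if score < threshold:
            continue
        prev = graph.get_edge_data(a, b)
        if prev is None or score > prev["score"]:
            graph.add_edge(a, b, score=score)
    return InteractionNetwork(
        graph=graph,
        threshold=threshold,
        meta={
            "string_dialect": string_dialect,
            "n_unmapped_dropped": n_unmapped,
            "n_self_edges_dropped": n_self,
        },
    )


def partners(network: InteractionNetwork, gene: str) -> set[str]:
    """Neighbors of a gene; empty set when the gene is absent."""
    if gene not in network.graph:
        return set()
    return set(network.graph.neighbors(gene))
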