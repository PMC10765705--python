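"""Normalized phylogenetic profiling (NPP).

A gene's phylogenetic profile is the pattern of conservation of its
orthologs across a panel of eukaryotic genomes.  The continuous NPP
variant used here starts from the best BLASTP hit bitscore of each human
gene against each species, normalizes it by the query protein's self-hit
bitscore, applies a log2 transform, and finally z-scores each species
column so that phylogenetic distance does not dominate the signal.

Co-evolution between two genes is the Pearson correlation of their rows
in the normalized matrix.  Correlations are computed both over all
species ("Eukaryota") and restricted to named clades of the eukaryotic
tree, because functionally linked genes often co-evolve only within a
part of the tree; the per-clade top partners are then merged, keeping
each partner's best rank across clades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BitscoreTable",
    "ConservationMatrix",
    "CladeMap",
    "CoevolutionResult",
    "CANONICAL_CLADES",
    "normalize_bitscores",
    "has_ortholog",
    "top_coevolved",
    "coevolution_profile",
    "default_min_species",
]

#: The 16 named clades spanning the eukaryotic tree used for clade-wise
#: profiling, in addition to the all-species "Eukaryota" superset.
CANONICAL_CLADES: tuple[str, ...] = (
    "Chordata",
    "Ecdysozoa",
    "Platyhelminthes",
    "Alveolates",
    "Stramenopiles",
    "Fungi",
    "Viridiplantae",
    "Mammalia",
    "Archelosuria",
    "Arthropoda",
    "Nematoda",
    "Basidiomycota",
    "Ascomycota",
    "Fungi incertae sedis",
    "Liliopsida",
    "Eudicotyledons",
)

EUKARYOTA = "Eukaryota"


class NppError(ValueError):
    """Raised for malformed profiling inputs."""


@dataclass
class BitscoreTable:
    """Raw best-hit bitscores for genes (rows) against species (columns).

    ``best_hit`` holds the bitscore of the best BLAST hit of each gene in
    each species; an absent hit is encoded as NaN.  ``self_hit`` is the
    bitscore of each query protein aligned to itself (always positive).
    """

    genes: list[str]
    species: list[str]
    best_hit: np.ndarray  # (n_genes, n_species), NaN = no hit
    self_hit: np.ndarray  # (n_genes,)

    def __post_init__(self) -> None:
        self.best_hit = np.asarray(self.best_hit, dtype=float)
        self.self_hit = np.asarray(self.self_hit, dtype=float)
        n_g, n_s = self.best_hit.shape
        if n_g != len(self.genes) or n_s != len(self.species):
            raise NppError(
                f"bitscore matrix is {self.best_hit.shape} but there are "
                f"{len(self.genes)} genes and {len(self.species)} species"
            )
        if self.self_hit.shape != (n_g,):
            raise NppError("self-hit vector length does not match gene count")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, self_hits_path: str | Path) -> "BitscoreTable":
        """Load from a genes x species TSV plus a (gene, bitscore) TSV."""
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sh = pd.read_csv(self_hits_path, sep="\t", index_col=0).iloc[:, 0]
        missing = [g for g in df.index if g not in sh.index]
        if missing:
            raise NppError(f"genes without a self-hit bitscore: {missing[:5]}")
        return cls(
            genes=list(df.index),
            species=list(df.columns),
            best_hit=df.to_numpy(dtype=float),
            self_hit=sh.loc[df.index].to_numpy(dtype=float),
        )


@dataclass
class ConservationMatrix:
    """Per-species z-scored, log2-normalized conservation scores.

    ``presence`` marks the entries backed by an observed best hit; all
    other entries were imputed before z-scoring.
    """

    genes: list[str]
    species: list[str]
    values: np.ndarray  # (n_genes, n_species)
    presence: np.ndarray  # boolean, same shape
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._species_index = {s: i for i, s in enumerate(self.species)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise NppError(f"unknown gene: {gene}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def species_columns(self, species: Iterable[str]) -> np.ndarray:
        """Column indices for the given species, ignoring absentees."""
        return np.array(
            [self._species_index[s] for s in species if s in self._species_index],
            dtype=int,
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.genes, columns=self.species).to_csv(
            path, sep="\t", index_label="gene"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationMatrix":
        """Load a pre-normalized matrix; all entries are taken as observed."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        return cls(
            genes=list(df.index),
            species=list(df.columns),
            values=values,
            presence=np.ones_like(values, dtype=bool),
            meta={"source": str(path)},
        )


@dataclass
class CladeMap:
    """Grouping of species into named clades plus the Eukaryota superset.

    Every non-Eukaryota clade must be a subset of Eukaryota.  When the
    Eukaryota entry is missing it is derived as the union of all listed
    clades.
    """

    clades: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.clades = {name: set(members) for name, members in self.clades.items()}
        if EUKARYOTA not in self.clades:
            universe: set[str] = set()
            for members in self.clades.values():
                universe |= members
            self.clades[EUKARYOTA] = universe
        universe = self.clades[EUKARYOTA]
        for name, members in self.clades.items():
            if name != EUKARYOTA and not members <= universe:
                raise NppError(f"clade {name!r} contains species outside Eukaryota")

    def __contains__(self, name: str) -> bool:
        return name in self.clades

    def __getitem__(self, name: str) -> set[str]:
        try:
            return self.clades[name]
        except KeyError:
            raise NppError(f"unknown clade: {name}") from None

    def names(self) -> list[str]:
        """Eukaryota first, remaining clades in sorted order."""
        rest = sorted(n for n in self.clades if n != EUKARYOTA)
        return [EUKARYOTA] + rest

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CladeMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["species", "clade"], comment="#")
        clades: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            clades.setdefault(str(row["clade"]), set()).add(str(row["species"]))
        return cls(clades)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.names():
                for sp in sorted(self.clades[name]):
                    fh.write(f"{sp}\t{name}\n")


@dataclass
class CoevolutionResult:
    """Per-clade top co-evolved partners of a query gene, plus the merge.

    ``per_clade`` maps clade name to a rank-ordered list of
    ``(partner, rank, r)``.  ``merged`` maps each unique partner to its
    best (lowest) rank over all clades and the clade achieving it.
    """

    query: str
    per_clade: dict[str, list[tuple[str, int, float]]]
    merged: dict[str, tuple[int, str]]

    @property
    def partners(self) -> set[str]:
        return set(self.merged)

    def edge_table(self) -> pd.DataFrame:
        """Long-form (query, partner, clade, rank, r) table for export."""
        rows = []
        for clade, entries in self.per_clade.items():
            for gene, rank, r in entries:
                rows.append((self.query, gene, clade, rank, r))
        return pd.DataFrame(rows, columns=["query", "partner", "clade", "rank", "r"])


def default_min_species(clade_size: int) -> int:
    """Presence threshold: at least 3 species, or 10% of the clade."""
    return max(3, math.ceil(0.10 * clade_size))


def normalize_bitscores(
    raw: BitscoreTable,
    missing_policy: str = "floor_epsilon",
    clip_ratio: bool = True,
) -> ConservationMatrix:
    """Turn raw best-hit bitscores into the normalized profile matrix.

    For an observed hit the value path is ``v = log2(best_hit / self_hit)``
    followed by per-species-column z-scoring (sample standard deviation,
    n-1 denominator).  Missing hits are imputed *before* z-scoring:

    - ``floor_epsilon``: column minimum of the log2 values minus 1, so an
      absent ortholog sorts strictly below every observed one;
    - ``column_min``: the column minimum itself.

    Ratios above 1 (a database hit scoring above the self-hit) are
    clipped to 1 when ``clip_ratio`` and counted in ``meta``.
    """
    if missing_policy not in ("floor_epsilon", "column_min"):
        raise NppError(f"unknown missing_policy: {missing_policy!r}")
    if np.any(~np.isfinite(raw.self_hit)) or np.any(raw.self_hit <= 0):
        bad = [raw.genes[i] for i in np.flatnonzero(~(raw.self_hit > 0))]
        raise NppError(f"non-positive self-hit bitscore for genes: {bad[:5]}")

    presence = np.isfinite(raw.best_hit)
    ratio = raw.best_hit / raw.self_hit[:, None]
    n_clipped = 0
    if clip_ratio:
        over = presence & (ratio > 1.0)
        n_clipped = int(over.sum())
        ratio = np.where(over, 1.0, ratio)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.log2(ratio)

    values = np.array(logv, dtype=float)
    for j, sp in enumerate(raw.species):
        col_obs = values[presence[:, j], j]
        if col_obs.size == 0:
            raise NppError(f"species column {sp!r} has no observed hits")
        cmin = float(np.min(col_obs))
        fill = cmin - 1.0 if missing_policy == "floor_epsilon" else cmin
        values[~presence[:, j], j] = fill
        sd = float(np.std(values[:, j], ddof=1)) if values.shape[0] > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            raise NppError(f"species column {sp!r} has zero variance after imputation")
        values[:, j] = (values[:, j] - float(np.mean(values[:, j]))) / sd

    return ConservationMatrix(
        genes=list(raw.genes),
        species=list(raw.species),
        values=values,
        presence=presence,
        meta={
            "missing_policy": missing_policy,
            "zscore_ddof": 1,
            "n_ratio_clipped": n_clipped,
        },
    )


def has_ortholog(
    matrix: ConservationMatrix,
    gene: str,
    clade: str,
    clade_map: CladeMap,
    min_species: int | None = None,
) -> bool:
    """Whether the gene has an observed best hit in enough clade species."""
    if gene not in matrix:
        raise NppError(f"unknown gene: {gene}")
    members = clade_map[clade]
    cols = matrix.species_columns(members)
    if min_species is None:
        min_species = default_min_species(len(cols))
    if min_species < 1:
        raise NppError("min_species must be >= 1")
    gi = matrix._gene_index[gene]
    return int(matrix.presence[gi, cols].sum()) >= min_species


def top_coevolved(
    matrix: ConservationMatrix,
    query: str,
    clade: str,
    clade_map: CladeMap,
    k: int = 50,
) -> list[tuple[str, int, float]]:
    """Top-k Pearson-correlated genes with the query within one clade.

    Correlations are computed over the full set of clade species columns
    of the fixed normalized matrix (imputed values included).  Ties in r
    are broken lexicographically by gene id; the query is excluded.
    """
    if k < 1:
        raise NppError("k must be >= 1")
    cols = matrix.species_columns(clade_map[clade])
    if len(cols) < 3:
        raise NppError(f"clade {clade!r} covers only {len(cols)} matrix species (< 3)")
    q = matrix.gene_row(query)[cols]
    q_c = q - q.mean()
    q_norm = float(np.sqrt((q_c**2).sum()))
    if q_norm == 0.0:
        raise NppError(f"query {query!r} has a constant profile within clade {clade!r}")

    sub = matrix.values[:, cols]
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = centered @ q_c / (norms * q_norm)
    r = np.where(np.isfinite(r), r, -np.inf)  # constant partners excluded

    qi = matrix._gene_index[query]
    order = sorted(
        (i for i in range(len(matrix.genes)) if i != qi and r[i] > -np.inf),
        key=lambda i: (-r[i], matrix.genes[i]),
    )
    return [
        (matrix.genes[i], rank, float(r[i]))
        for rank, i in enumerate(order[:k], start=1)
    ]


def coevolution_profile(
    matrix: ConservationMatrix,
    query: str,
    clade_map: CladeMap,
    k: int = 50,
    min_species: int | None = None,
) -> CoevolutionResult:
    """Run the per-clade retrieval in every clade where the query has an
    ortholog (Eukaryota included) and merge partners by best rank."""
    if query not in matrix:
        raise NppError(f"unknown gene: {query}")
    per_clade: dict[str, list[tuple[str, int, float]]] = {}
    for clade in clade_map.names():
        if not has_ortholog(matrix, query, clade, clade_map, min_species):
            continue
        try:
            per_clade[clade] = top_coevolved(matrix, query, clade, clade_map, k)
        except NppError:
            # degenerate clade (too few columns / constant query row)
            continue
    if not per_clade:
        raise NppError(f"no clade coverage for query {query!r}")

    merged: dict[str, tuple[int, str]] = {}
    for clade in sorted(per_clade):  # deterministic clade tie-break
        for gene, rank, _r in per_clade[clade]:
            if gene not in merged or rank < merged[gene][0]:
                merged[gene] = (rank, clade)
    return CoevolutionResult(query=query, per_clade=per_clade, merged=merged)
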