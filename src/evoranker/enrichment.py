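"""One-sided KS enrichment and combined-probability candidate ranking.

For each patient candidate gene we ask whether its functionally linked
genes — the merged co-evolved partners and the network interaction
partners — sit unusually high in the patient's phenotype-similarity
ranking.  With i the linked-gene sample and j the reference of all
ranked genes, the one-sided two-sample Kolmogorov-Smirnov statistic is

    D- = max(0, sup_x [Fj(x) - Fi(x)])

which is large when the sample ECDF lags the reference, i.e. when the
sample concentrates at high similarity scores.  The co-evolution and
network p-values are combined per candidate with Fisher's method,

    X^2_(2k) = -2 * sum_i ln(p_i),

(or optionally Simes' method) and candidates are ranked by the combined
p-value, most significant first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .npp import CoevolutionResult
from .phenotype import PhenotypeRanking

__all__ = [
    "KSResult",
    "CombinedScore",
    "EnrichmentResult",
    "ks_one_sided",
    "fisher_combine",
    "simes_combine",
    "prioritize",
]

#: Exact permutation enumeration is used at or below this pooled size.
EXACT_CAP = 16

#: p-values are floored here before taking logs (with a warning).
P_FLOOR = 1e-300

#: KS samples smaller than this are skipped as uninformative.
MIN_OVERLAP = 3


class EnrichmentError(ValueError):
    pass


@dataclass
class KSResult:
    d_minus: float
    p_value: float
    n_sample: int
    n_reference: int
    method: str  # "asymptotic" | "exact_permutation"


@dataclass
class CombinedScore:
    components: list[tuple[str, float]]
    statistic: float
    df: int
    p_combined: float
    method: str  # "fisher" | "simes"


@dataclass
class EnrichmentResult:
    """Per-candidate KS evidence, combined p, and the final ranking."""

    candidates: dict[str, dict] = field(default_factory=dict)
    ordering: list[str] = field(default_factory=list)

    def rank_of(self, gene: str) -> int:
        return self.ordering.index(gene) + 1

    def to_frame(self):
        import pandas as pd
        from statsmodels.stats.multitest import multipletests

        rows = []
        for rank, gene in enumerate(self.ordering, start=1):
            c = self.candidates[gene]
            coevo, string, comb = c.get("coevo_ks"), c.get("string_ks"), c["combined"]
            rows.append(
                {
                    "candidate": gene,
                    "p_coevo": coevo.p_value if coevo else float("nan"),
                    "p_string": string.p_value if string else float("nan"),
                    "statistic": comb.statistic if comb else float("nan"),
                    "df": comb.df if comb else 0,
                    "p_combined": c["p_combined"],
                    "rank": rank,
                    "flags": ";".join(c["flags"]),
                }
            )
        df = pd.DataFrame(rows)
        if len(df):
            df["p_bh"] = multipletests(df["p_combined"], method="fdr_bh")[1]
        return df


def _d_minus(sample: np.ndarray, reference: np.ndarray) -> float:
    """sup_x [Fj(x) - Fi(x)] clipped at 0, over pooled unique values.

    Both ECDFs are right-continuous step functions; the sup over all x is
    attained at a pooled data value.
    """
    grid = np.unique(np.concatenate([sample, reference]))
    fi = np.searchsorted(np.sort(sample), grid, side="right") / sample.size
    fj = np.searchsorted(np.sort(reference), grid, side="right") / reference.size
    return float(max(0.0, np.max(fj - fi)))


def _exact_permutation_p(pooled: np.ndarray, n: int, d_obs: float) -> float:
    """P(D- >= d_obs) under uniformly random sample/reference labels.

    Vectorized over all C(n+m, n) label assignments: for each assignment
    the ECDF difference is evaluated on the pooled unique values.
    """
    size = pooled.size
    grid = np.unique(pooled)
    le = (pooled[:, None] <= grid[None, :]).astype(float)  # size x n_grid
    combs = np.array(list(combinations(range(size), n)), dtype=int)
    mask = np.zeros((len(combs), size))
    mask[np.arange(len(combs))[:, None], combs] = 1.0
    fi = (mask @ le) / n
    fj = ((1.0 - mask) @ le) / (size - n)
    d = np.clip((fj - fi).max(axis=1), 0.0, None)
    return float((d >= d_obs - 1e-12).mean())


def ks_one_sided(
    sample_scores: Sequence[float],
    reference_scores: Sequence[float],
    method: str = "auto",
    exact_cap: int = EXACT_CAP,
) -> KSResult:
    """One-sided two-sample KS test for sample shifted to high scores.

    H0: Fi(x) >= Fj(x) for all x; H1: Fi(x) < Fj(x) for some x (the
    sample ECDF lies below the reference, i.e. the sample concentrates
    at the high-score end).  The p-value comes from the asymptotic
    one-sided bound ``exp(-2 d^2 nm/(n+m))``, or from exhaustive
    label-permutation enumeration when ``n + m <= exact_cap`` (or when
    ``method="exact_permutation"`` is forced).
    """
    sample = np.asarray(sample_scores, dtype=float)
    reference = np.asarray(reference_scores, dtype=float)
    if sample.size < 1:
        raise EnrichmentError("empty KS sample")
    if reference.size < 2:
        raise EnrichmentError("KS reference needs at least 2 values")

    d = _d_minus(sample, reference)
    n, m = sample.size, reference.size
    if method == "auto":
        method = "exact_permutation" if n + m <= exact_cap else "asymptotic"
    if method == "exact_permutation":
        if n + m > max(exact_cap, 24):
            raise EnrichmentError("pooled size too large for exact enumeration")
        pooled = np.concatenate([sample, reference])
        p = _exact_permutation_p(pooled, n, d)
    elif method == "asymptotic":
        p = float(np.exp(-2.0 * d * d * n * m / (n + m)))
    else:
        raise EnrichmentError(f"unknown KS method: {method!r}")
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return KSResult(d_minus=d, p_value=p, n_sample=n, n_reference=m, method=method)


def _check_ps(p_values: Sequence[float]) -> list[float]:
    ps = list(map(float, p_values))
    if not ps:
        raise EnrichmentError("no p-values to combine")
    for p in ps:
        if p == 0.0:
            raise EnrichmentError("p = 0 cannot be combined; floor it first")
        if not (0.0 < p <= 1.0):
            raise EnrichmentError(f"p-value out of (0, 1]: {p}")
    return ps


def fisher_combine(
    p_values: Sequence[float], names: Sequence[str] | None = None
) -> CombinedScore:
    """Fisher's combined probability test: chi-square with 2k df."""
    ps = _check_ps(p_values)
    k = len(ps)
    statistic = -2.0 * sum(math.log(p) for p in ps)
    p_combined = float(stats.chi2.sf(statistic, 2 * k))
    p_combined = min(1.0, max(p_combined, np.nextafter(0, 1)))
    names = list(names) if names is not None else [f"p{i+1}" for i in range(k)]
    return CombinedScore(
        components=list(zip(names, ps)),
        statistic=statistic,
        df=2 * k,
        p_combined=p_combined,
        method="fisher",
    )


def simes_combine(
    p_values: Sequence[float], names: Sequence[str] | None = None
) -> CombinedScore:
    """Simes' combination: min_i k * p_(i) / i over the sorted p's."""
    ps = _check_ps(p_values)
    k = len(ps)
    p_combined = min(k * p / (i + 1) for i, p in enumerate(sorted(ps)))
    p_combined = min(1.0, p_combined)
    names = list(names) if names is not None else [f"p{i+1}" for i in range(k)]
    return CombinedScore(
        components=list(zip(names, ps)),
        statistic=p_combined,
        df=0,
        p_combined=p_combined,
        method="simes",
    )


def _floored(p: float, gene: str, source: str) -> float:
    if p < P_FLOOR:
        warnings.warn(
            f"{source} p-value for {gene} below {P_FLOOR}; floored before combining"
        )
        return P_FLOOR
    return p


def prioritize(
    candidates: Sequence[str],
    ranking: PhenotypeRanking,
    coevo: Mapping[str, CoevolutionResult | None],
    network_partners: Mapping[str, Iterable[str]],
    combine_method: str = "fisher",
    min_overlap: int = MIN_OVERLAP,
) -> EnrichmentResult:
    """Rank candidate genes by combined co-evolution + network enrichment.

    Per candidate, the KS sample is the phenotype-similarity scores of
    its merged co-evolved partners (resp. network partners) restricted
    to the ranked universe; the reference is the scores of all ranked
    genes.  Sources with fewer than ``min_overlap`` genes in the
    universe are skipped (k adapts); a candidate with no usable source
    is flagged ``no_evidence`` and placed last with p = 1.  Duplicate
    partners are counted once.
    """
    if not candidates:
        raise EnrichmentError("no candidate genes")
    combine = {"fisher": fisher_combine, "simes": simes_combine}.get(combine_method)
    if combine is None:
        raise EnrichmentError(f"unknown combine method: {combine_method!r}")

    reference = np.array([ranking.scores[g] for g in ranking.ordering])
    universe = ranking.universe
    result = EnrichmentResult()
    for gene in candidates:
        entry: dict = {"coevo_ks": None, "string_ks": None, "combined": None, "flags": []}
        sources: list[tuple[str, KSResult]] = []

        profile = coevo.get(gene)
        if profile is not None:
            hits = sorted(profile.partners & universe)
            if len(hits) >= min_overlap:
                ks = ks_one_sided([ranking.scores[g] for g in hits], reference)
                entry["coevo_ks"] = ks
                sources.append(("coevolution", ks))
            else:
                entry["flags"].append("coevo_insufficient_overlap")
        else:
            entry["flags"].append("no_coevolution_profile")

        partners = set(network_partners.get(gene, ())) - {gene}
        hits = sorted(partners & universe)
        if len(hits) >= min_overlap:
            ks = ks_one_sided([ranking.scores[g] for g in hits], reference)
            entry["string_ks"] = ks
            sources.append(("network", ks))
        else:
            entry["flags"].append("network_insufficient_overlap")

        if sources:
            combined = combine(
                [_floored(ks.p_value, gene, name) for name, ks in sources],
                names=[name for name, _ in sources],
            )
            entry["combined"] = combined
            entry["p_combined"] = combined.p_combined
        else:
            entry["flags"].append("no_evidence")
            entry["p_combined"] = 1.0
        result.candidates[gene] = entry

    result.ordering = sorted(
        result.candidates,
        key=lambda g: (
            result.candidates[g]["p_combined"],
            "no_evidence" in result.candidates[g]["flags"],
            g,
        ),
    )
    return result
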