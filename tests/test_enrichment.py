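import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoranker.enrichment import (
    EnrichmentError,
    fisher_combine,
    ks_one_sided,
    prioritize,
    simes_combine,
)
from evoranker.phenotype import PhenotypeRanking


def _ranking(scores: dict) -> PhenotypeRanking:
    ordering = sorted(scores, key=lambda g: (-scores[g], g))
    return PhenotypeRanking(query_terms=set(), scores=scores, ordering=ordering)


def brute_d_minus(sample, reference):
    """Independent oracle: scan every pooled value explicitly."""
    best = 0.0
    for x in sorted(set(sample) | set(reference)):
        fi = sum(s <= x for s in sample) / len(sample)
        fj = sum(s <= x for s in reference) / len(reference)
        best = max(best, fj - fi)
    return best


class TestKS:
    def test_identical_samples_null(self):
        r = ks_one_sided([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert r.d_minus == 0.0
        assert r.p_value == 1.0

    def test_sample_above_reference_exact(self):
        # both sample values exceed all reference values: D- = 1 and the
        # permutation p is 1/C(6,2) = 1/15
        r = ks_one_sided([0.8, 0.9], [0.1, 0.2, 0.3, 0.4])
        assert r.method == "exact_permutation"
        assert r.d_minus == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1 / 15)

    def test_sample_below_reference_is_null_direction(self):
        r = ks_one_sided([0.05, 0.07], [0.5, 0.6, 0.7, 0.8])
        assert r.d_minus == 0.0
        assert r.p_value == 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(EnrichmentError, match="empty"):
            ks_one_sided([], [0.1, 0.2])
        with pytest.raises(EnrichmentError, match="reference"):
            ks_one_sided([0.1], [0.2])

    def test_exact_matches_enumeration_oracle(self):
        # every split of an 8-value pool: D- and permutation p both equal
        # the brute-force enumeration
        rng = np.random.default_rng(3)
        pool = rng.random(8)
        idx = range(8)
        for n in range(1, 7):
            for comb in combinations(idx, n):
                sample = [pool[i] for i in comb]
                reference = [pool[i] for i in idx if i not in comb]
                got = ks_one_sided(sample, reference, method="exact_permutation")
                assert got.d_minus == pytest.approx(brute_d_minus(sample, reference))
                hits = total = 0
                for c2 in combinations(idx, n):
                    s2 = [pool[i] for i in c2]
                    r2 = [pool[i] for i in idx if i not in c2]
                    total += 1
                    if brute_d_minus(s2, r2) >= got.d_minus - 1e-12:
                        hits += 1
                assert got.p_value == pytest.approx(hits / total)

    @given(
        data=st.data(),
        shift=st.integers(-5, 5),
        scale=st.integers(1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_d_invariant_under_increasing_transform(self, data, shift, scale):
        # scores on a 1/64 grid so the affine map is injective in floats
        grid = st.integers(0, 64).map(lambda i: i / 64)
        sample = data.draw(st.lists(grid, min_size=2, max_size=10))
        reference = data.draw(st.lists(grid, min_size=3, max_size=15))
        base = ks_one_sided(sample, reference, method="asymptotic").d_minus
        f = lambda xs: [scale * x + shift for x in xs]  # strictly increasing
        transformed = ks_one_sided(f(sample), f(reference), method="asymptotic").d_minus
        assert transformed == pytest.approx(base, abs=1e-12)

    def test_type_one_error_calibrated(self):
        # sample drawn from the reference universe: ~5% of p-values at
        # the 0.05 level over 1,000 seeded replicates
        rng = np.random.default_rng(0)
        reference = rng.random(500)
        hits = sum(
            ks_one_sided(rng.choice(reference, 30, replace=False), reference).p_value
            < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07


class TestFisher:
    def test_single_p_identity(self):
        # chi-square df=2 survival of -2 ln p is exactly p
        for p in (1e-15, 1e-6, 0.01, 0.3, 0.99):
            assert fisher_combine([p]).p_combined == pytest.approx(p, rel=1e-12)

    def test_two_component_closed_form(self):
        # df=4 survival has closed form exp(-x/2) (1 + x/2)
        ps = [0.05, 0.05]
        x = -2 * sum(math.log(p) for p in ps)
        expect = math.exp(-x / 2) * (1 + x / 2)
        got = fisher_combine(ps)
        assert got.statistic == pytest.approx(x)
        assert got.df == 4
        assert got.p_combined == pytest.approx(expect, rel=1e-12)

    def test_published_combination(self):
        # coevolution p 7.93e-15 with network p 0.53 combine to 1.42e-13
        # (2% ratio check: the 3-sig-fig inputs carry ~1% rounding error)
        got = fisher_combine([7.93e-15, 0.53]).p_combined
        assert abs(got / 1.42e-13 - 1.0) < 0.02

    def test_permutation_invariant(self):
        a = fisher_combine([0.01, 0.5, 0.2]).p_combined
        b = fisher_combine([0.2, 0.01, 0.5]).p_combined
        assert a == b

    def test_adding_null_component_is_harmless_but_tracked(self):
        base = fisher_combine([0.01])
        padded = fisher_combine([0.01, 1.0])
        assert padded.df == 4
        assert padded.statistic == pytest.approx(base.statistic)
        assert padded.p_combined > base.p_combined  # df penalty only

    def test_zero_p_rejected(self):
        with pytest.raises(EnrichmentError, match="floor"):
            fisher_combine([0.0, 0.5])


class TestSimes:
    def test_formula_examples(self):
        assert simes_combine([0.25]).p_combined == pytest.approx(0.25)
        assert simes_combine([0.01, 0.04]).p_combined == pytest.approx(0.02)
        assert simes_combine([0.3, 0.3, 0.3]).p_combined == pytest.approx(0.3)

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            k = int(rng.integers(1, 7))
            ps = rng.uniform(1e-6, 1.0, size=k)
            got = simes_combine(list(ps)).p_combined
            srt = np.sort(ps)
            expect = min(min(k * srt[i] / (i + 1) for i in range(k)), 1.0)
            assert got == pytest.approx(expect, rel=1e-12)


class TestPrioritize:
    def setup_method(self):
        rng = np.random.default_rng(7)
        genes = [f"u{i:03d}" for i in range(60)]
        self.ranking = _ranking({g: float(s) for g, s in zip(genes, rng.random(60))})
        self.top = self.ranking.ordering[:8]

    def test_single_candidate_ranks_first(self):
        from evoranker.npp import CoevolutionResult

        coevo = CoevolutionResult(
            query="cand",
            per_clade={"Eukaryota": [(g, i + 1, 0.9) for i, g in enumerate(self.top)]},
            merged={g: (i + 1, "Eukaryota") for i, g in enumerate(self.top)},
        )
        res = prioritize(["cand"], self.ranking, {"cand": coevo}, {"cand": set()})
        assert res.ordering == ["cand"]

    def test_enriched_candidate_beats_random_one(self):
        from evoranker.npp import CoevolutionResult

        rng = np.random.default_rng(1)
        rand = list(rng.choice(self.ranking.ordering, 8, replace=False))
        mk = lambda q, ps: CoevolutionResult(
            query=q,
            per_clade={"Eukaryota": [(g, i + 1, 0.5) for i, g in enumerate(ps)]},
            merged={g: (i + 1, "Eukaryota") for i, g in enumerate(ps)},
        )
        res = prioritize(
            ["good", "rand"],
            self.ranking,
            {"good": mk("good", self.top), "rand": mk("rand", rand)},
            {"good": set(), "rand": set()},
        )
        assert res.ordering[0] == "good"

    def test_insufficient_overlap_skips_source(self):
        from evoranker.npp import CoevolutionResult

        coevo = CoevolutionResult(
            query="cand",
            per_clade={"Eukaryota": [("u000", 1, 0.9), ("zzz", 2, 0.8)]},
            merged={"u000": (1, "Eukaryota"), "zzz": (2, "Eukaryota")},
        )
        res = prioritize(
            ["cand"], self.ranking, {"cand": coevo}, {"cand": set(self.top)}
        )
        entry = res.candidates["cand"]
        assert "coevo_insufficient_overlap" in entry["flags"]
        assert entry["combined"].df == 2  # only the network source remains

    def test_no_evidence_flagged_and_last(self):
        from evoranker.npp import CoevolutionResult

        coevo = CoevolutionResult(
            query="a",
            per_clade={"Eukaryota": [(g, i + 1, 0.9) for i, g in enumerate(self.top)]},
            merged={g: (i + 1, "Eukaryota") for i, g in enumerate(self.top)},
        )
        res = prioritize(
            ["a", "b"], self.ranking, {"a": coevo, "b": None}, {"a": set(), "b": set()}
        )
        entry = res.candidates["b"]
        assert "no_evidence" in entry["flags"]
        assert entry["p_combined"] == 1.0
        assert res.ordering[-1] == "b"

    def test_duplicate_partners_counted_once(self):
        from evoranker.npp import CoevolutionResult

        # same partner at different ranks in two clades: one KS sample point
        coevo = CoevolutionResult(
            query="cand",
            per_clade={
                "Fungi": [(g, i + 1, 0.9) for i, g in enumerate(self.top[:4])],
                "Chordata": [(g, i + 1, 0.8) for i, g in enumerate(self.top[:4])],
            },
            merged={g: (i + 1, "Chordata") for i, g in enumerate(self.top[:4])},
        )
        res = prioritize(["cand"], self.ranking, {"cand": coevo}, {"cand": set()})
        assert res.candidates["cand"]["coevo_ks"].n_sample == 4

    def test_simes_combination_selectable(self):
        res = prioritize(
            ["cand"], self.ranking, {"cand": None}, {"cand": set(self.top)},
            combine_method="simes",
        )
        assert res.candidates["cand"]["combined"].method == "simes"
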