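import math

import numpy as np
import pytest

from evoranker.npp import (
    BitscoreTable,
    CladeMap,
    NppError,
    coevolution_profile,
    default_min_species,
    has_ortholog,
    normalize_bitscores,
    top_coevolved,
)


def _table(best, self_hit=None, n_species=None):
    best = np.asarray(best, dtype=float)
    n_g, n_s = best.shape
    return BitscoreTable(
        genes=[f"g{i}" for i in range(n_g)],
        species=[f"s{j}" for j in range(n_s)],
        best_hit=best,
        self_hit=np.asarray(self_hit if self_hit is not None else [400.0] * n_g),
    )


class TestNormalize:
    def test_log2_ratio_values(self):
        # self-hit ratio 1 -> log2 0; ratio 1/4 -> log2 -2, checked
        # before z-scoring via a column with a known value spread
        bt = _table([[400.0], [100.0], [25.0]], self_hit=[400.0, 400.0, 400.0])
        cm = normalize_bitscores(bt)
        # pre-z values are {0, -2, -4}: z-scores under sample sd (n-1)
        pre = np.array([0.0, -2.0, -4.0])
        expected = (pre - pre.mean()) / pre.std(ddof=1)
        np.testing.assert_allclose(cm.values[:, 0], expected, atol=1e-12)

    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        best = 300.0 * np.exp2(np.minimum(0.0, -2 + rng.standard_normal((20, 6))))
        cm = normalize_bitscores(_table(best, self_hit=[300.0] * 20))
        np.testing.assert_allclose(cm.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(cm.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("policy,offset", [("floor_epsilon", -1.0), ("column_min", 0.0)])
    def test_missing_imputed_below_observed(self, policy, offset):
        best = np.array([[400.0], [100.0], [np.nan]])
        bt = _table(best, self_hit=[400.0] * 3)
        cm = normalize_bitscores(bt, missing_policy=policy)
        assert not cm.presence[2, 0]
        # recover pre-z value ordering: imputed = column min + offset
        pre = np.array([0.0, -2.0, -2.0 + offset])
        expected = (pre - pre.mean()) / pre.std(ddof=1)
        np.testing.assert_allclose(cm.values[:, 0], expected, atol=1e-12)

    def test_ratio_above_one_clipped(self):
        bt = _table([[500.0], [100.0], [25.0]], self_hit=[400.0] * 3)
        cm = normalize_bitscores(bt)
        assert cm.meta["n_ratio_clipped"] == 1
        assert cm.values[0, 0] == cm.values.max(axis=0)[0]

    def test_nonpositive_self_hit_rejected(self):
        bt = _table([[10.0], [10.0]], self_hit=[400.0, 0.0])
        with pytest.raises(NppError, match="self-hit"):
            normalize_bitscores(bt)

    def test_zero_variance_column_named(self):
        bt = _table([[400.0, 400.0], [400.0, 100.0]], self_hit=[400.0, 400.0])
        with pytest.raises(NppError, match="s0"):
            normalize_bitscores(bt)


class TestCladeMap:
    def test_eukaryota_derived_as_union(self):
        cm = CladeMap({"Fungi": {"a", "b"}, "Chordata": {"c"}})
        assert cm["Eukaryota"] == {"a", "b", "c"}

    def test_subset_invariant_enforced(self):
        with pytest.raises(NppError, match="outside"):
            CladeMap({"Eukaryota": {"a"}, "Fungi": {"a", "b"}})

    def test_default_min_species(self):
        assert default_min_species(10) == 3
        assert default_min_species(200) == 20


class TestHasOrtholog:
    def test_threshold_boundary(self, small_matrix):
        matrix, clades = small_matrix
        # remove presence for gene g0 in CladeA except one species
        matrix.presence[0, :3] = [True, False, False]
        assert has_ortholog(matrix, "g0", "CladeA", clades, min_species=1)
        assert not has_ortholog(matrix, "g0", "CladeA", clades, min_species=2)
        matrix.presence[0, :3] = False
        assert not has_ortholog(matrix, "g0", "CladeA", clades, min_species=1)

    def test_unknown_gene_and_clade(self, small_matrix):
        matrix, clades = small_matrix
        with pytest.raises(NppError):
            has_ortholog(matrix, "nope", "CladeA", clades, 1)
        with pytest.raises(NppError):
            has_ortholog(matrix, "g0", "Metazoa", clades, 1)


class TestTopCoevolved:
    def test_matches_bruteforce_pearson(self, small_matrix):
        matrix, clades = small_matrix
        for clade in ("CladeA", "CladeB", "Eukaryota"):
            cols = matrix.species_columns(clades[clade])
            sub = matrix.values[:, cols]
            got = top_coevolved(matrix, "g0", clade, clades, k=9)
            # independent oracle: full all-pairs corrcoef + explicit sort
            r_all = np.corrcoef(sub)[0]
            expect = sorted(
                ((matrix.genes[i], r_all[i]) for i in range(1, 10)),
                key=lambda t: (-t[1], t[0]),
            )
            assert [g for g, _ in expect] == [g for g, _, _ in got]
            np.testing.assert_allclose([r for _, r in expect], [r for _, _, r in got],
                                       atol=1e-12)

    def test_identical_row_ranks_first_with_r_one(self, small_matrix):
        matrix, clades = small_matrix
        matrix.values[5] = matrix.values[0]
        got = top_coevolved(matrix, "g0", "CladeB", clades, k=3)
        assert got[0][0] == "g5"
        assert got[0][2] == pytest.approx(1.0)

    def test_query_excluded_and_ranks_contiguous(self, small_matrix):
        matrix, clades = small_matrix
        got = top_coevolved(matrix, "g3", "Eukaryota", clades, k=9)
        assert "g3" not in {g for g, _, _ in got}
        assert [rank for _, rank, _ in got] == list(range(1, 10))

    def test_prefix_nesting_across_k(self, small_matrix):
        matrix, clades = small_matrix
        small = top_coevolved(matrix, "g1", "Eukaryota", clades, k=4)
        big = top_coevolved(matrix, "g1", "Eukaryota", clades, k=9)
        assert big[:4] == small

    def test_pearson_symmetry(self, small_matrix):
        matrix, clades = small_matrix
        r_ab = dict((g, r) for g, _, r in top_coevolved(matrix, "g2", "CladeC", clades, 9))
        r_ba = dict((g, r) for g, _, r in top_coevolved(matrix, "g7", "CladeC", clades, 9))
        assert r_ab["g7"] == pytest.approx(r_ba["g2"], abs=1e-12)

    def test_degenerate_inputs_rejected(self, small_matrix):
        matrix, clades = small_matrix
        tiny = CladeMap({"Tiny": set(matrix.species[:2]),
                         "Eukaryota": set(matrix.species)})
        with pytest.raises(NppError, match="< 3"):
            top_coevolved(matrix, "g0", "Tiny", tiny, k=5)
        matrix.values[4, :3] = 1.234  # constant within CladeA
        with pytest.raises(NppError, match="constant"):
            top_coevolved(matrix, "g4", "CladeA", clades, k=5)


class TestCoevolutionProfile:
    def test_merged_keeps_best_rank_and_clade(self, small_matrix):
        matrix, clades = small_matrix
        profile = coevolution_profile(matrix, "g0", clades, k=5, min_species=1)
        for gene, (best, clade) in profile.merged.items():
            ranks = [
                rank
                for c, entries in profile.per_clade.items()
                for g, rank, _ in entries
                if g == gene
            ]
            assert best == min(ranks)
            assert any(
                g == gene and rank == best for g, rank, _ in profile.per_clade[clade]
            )

    def test_clades_without_ortholog_skipped(self, small_matrix):
        matrix, clades = small_matrix
        matrix.presence[0, 3:6] = False  # wipe CladeB presence for g0
        profile = coevolution_profile(matrix, "g0", clades, k=3, min_species=3)
        assert "CladeB" not in profile.per_clade
        assert "Eukaryota" in profile.per_clade

    def test_no_clade_coverage_is_an_error(self, small_matrix):
        matrix, clades = small_matrix
        matrix.presence[0, :] = False
        with pytest.raises(NppError, match="no clade coverage"):
            coevolution_profile(matrix, "g0", clades, k=3, min_species=1)

    def test_planted_module_fully_recovered(self):
        from evoranker.synth import default_clade_map, gen_conservation_matrix

        module = [f"G{i:04d}" for i in range(10)]
        _, clade_map = default_clade_map(60, 2)
        _, matrix = gen_conservation_matrix(
            100, 60, clade_map=clade_map, seed=5,
            modules=[(module, 0.95, ["Chordata"])], missing_rate=0.0,
        )
        profile = coevolution_profile(matrix, "G0000", clade_map, k=9)
        assert set(module[1:]) <= profile.partners
        chordata = {g for g, _, _ in profile.per_clade["Chordata"]}
        assert chordata == set(module[1:])
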