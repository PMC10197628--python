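import itertools

import numpy as np
import pandas as pd
import pytest

from pantissue import (
    CorrelationTable,
    DataError,
    GeneSetCollection,
    gsea_preranked,
    ora,
    rank_genes,
    top_correlates,
)
from oracles import es_reference, hypergeom_upper_tail


def _ranked(genes, weights):
    return pd.DataFrame({"gene": genes, "weight": weights})


def _sets(**kw):
    coll = GeneSetCollection()
    for name, genes in kw.items():
        coll.add(name, "", genes)
    return coll


def _table(rows):
    df = pd.DataFrame(rows, columns=["tissue", "gene", "bicor", "n", "p", "q"])
    return CorrelationTable("liver", "SEED", df)


class TestRankGenes:
    def test_descending_by_coefficient(self):
        tab = _table([("liver", "a", 0.9, 50, 0.1, 0.1),
                      ("liver", "b", -0.2, 50, 0.1, 0.1),
                      ("liver", "c", 0.5, 50, 0.1, 0.1)])
        ranked = rank_genes(tab, "liver")
        assert list(ranked["gene"]) == ["a", "c", "b"]

    def test_ties_break_lexicographically(self):
        tab = _table([("liver", "zzz", 0.5, 50, 0.1, 0.1),
                      ("liver", "aaa", 0.5, 50, 0.1, 0.1)])
        ranked = rank_genes(tab, "liver")
        assert list(ranked["gene"]) == ["aaa", "zzz"]

    def test_absent_tissue_errors(self):
        tab = _table([("liver", "a", 0.9, 50, 0.1, 0.1)])
        with pytest.raises(DataError, match="adipose"):
            rank_genes(tab, "adipose")


class TestEnrichmentScore:
    def test_top_two_of_four_matches_hand_enumeration(self):
        """4-gene list with weights (4,3,2,1), set = top 2: running sum is
        +4/7, +7/7, then -1/2 per miss -> ES = 1.0."""
        ranked = _ranked(["a", "b", "c", "d"], [4.0, 3.0, 2.0, 1.0])
        res, _ = gsea_preranked(ranked, _sets(S=["a", "b"]), n_perm=50,
                                seed=0, min_set_size=1)
        es = res.iloc[0]["es"]
        assert es == pytest.approx(1.0)
        assert es == pytest.approx(
            es_reference([4, 3, 2, 1], [True, True, False, False]))

    def test_matches_brute_force_oracle_on_random_small_cases(self, rng):
        for _ in range(50):
            L = int(rng.integers(4, 9))
            weights = np.sort(rng.normal(size=L))[::-1]
            genes = [f"g{i}" for i in range(L)]
            K = int(rng.integers(1, L))
            members = list(rng.choice(genes, size=K, replace=False))
            ranked = _ranked(genes, weights)
            res, _ = gsea_preranked(ranked, _sets(S=members), n_perm=10,
                                    seed=1, min_set_size=1)
            is_hit = [g in set(members) for g in genes]
            assert res.iloc[0]["es"] == pytest.approx(
                es_reference(weights, is_hit), abs=1e-12)

    def test_es_invariant_to_positive_rescaling(self):
        genes = list("abcdefgh")
        w = np.array([5.0, 3.0, 2.0, 1.0, -0.5, -1.0, -2.0, -4.0])
        sets = _sets(S=["b", "c", "g"])
        r1, _ = gsea_preranked(_ranked(genes, w), sets, n_perm=20, seed=0,
                               min_set_size=1)
        r2, _ = gsea_preranked(_ranked(genes, 7.3 * w), sets, n_perm=20, seed=0,
                               min_set_size=1)
        assert r1.iloc[0]["es"] == pytest.approx(r2.iloc[0]["es"], abs=1e-12)

    def test_negating_weights_negates_es(self):
        genes = list("abcdef")
        w = np.array([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        sets = _sets(S=["a", "b"])
        # negated weights reverse the ranking; rebuild in ranked order
        r1, _ = gsea_preranked(_ranked(genes, w), sets, n_perm=20, seed=0,
                               min_set_size=1)
        r2, _ = gsea_preranked(_ranked(genes[::-1], -w[::-1]), sets, n_perm=20,
                               seed=0, min_set_size=1)
        assert r2.iloc[0]["es"] == pytest.approx(-r1.iloc[0]["es"], abs=1e-12)

    def test_leading_edge_is_subset_of_members_in_universe(self, rng):
        genes = [f"g{i}" for i in range(20)]
        w = np.sort(rng.normal(size=20))[::-1]
        members = ["g0", "g1", "g2", "g5", "g11", "not_in_universe"]
        res, _ = gsea_preranked(_ranked(genes, w), _sets(S=members), n_perm=20,
                                seed=0, min_set_size=1)
        le = set(res.iloc[0]["leading_edge"])
        assert le <= (set(members) & set(genes))
        assert len(le) >= 1


class TestPermutationP:
    def test_p_converges_to_exact_enumeration_on_tiny_universe(self):
        """For L=7, K=2 the label-permutation null has C(7,2)=21 equally
        likely position sets; the permutation p at 10,000 draws must sit
        within 3 binomial SEs of the exact same-sign tail."""
        genes = [f"g{i}" for i in range(7)]
        w = np.array([3.0, 2.5, 1.5, 0.8, -0.4, -1.0, -2.0])
        members = ["g0", "g2"]
        res, _ = gsea_preranked(_ranked(genes, w), _sets(S=members),
                                n_perm=10_000, seed=4, min_set_size=1)
        es, p = res.iloc[0]["es"], res.iloc[0]["p"]
        null = []
        for pos in itertools.combinations(range(7), 2):
            hit = [i in pos for i in range(7)]
            null.append(es_reference(w, hit))
        null = np.array(null)
        same = null * np.sign(es) > 0
        exact = (np.abs(null[same]) >= abs(es) - 1e-9).sum() / same.sum()
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(p - exact) <= 3 * se + 1 / 10_000

    def test_nes_sign_matches_es_sign(self, rng):
        genes = [f"g{i}" for i in range(30)]
        w = np.sort(rng.normal(size=30))[::-1]
        sets = _sets(UP=genes[:6], DOWN=genes[-6:])
        res, _ = gsea_preranked(_ranked(genes, w), sets, n_perm=200, seed=0)
        for _, row in res.iterrows():
            if np.isfinite(row["nes"]):
                assert np.sign(row["nes"]) == np.sign(row["es"])

    def test_small_sets_and_empty_overlap_are_skipped(self):
        genes = [f"g{i}" for i in range(10)]
        w = np.linspace(1, -1, 10)
        sets = _sets(EMPTY=["x", "y", "z"], TINY=["g0", "g1"],
                     OK=["g0", "g1", "g2", "g3", "g4"])
        res, skipped = gsea_preranked(_ranked(genes, w), sets, n_perm=20, seed=0)
        assert set(skipped) == {"EMPTY", "TINY"}
        assert list(res["name"]) == ["OK"]

    def test_too_few_permutations_rejected(self):
        ranked = _ranked(["a", "b"], [1.0, -1.0])
        with pytest.raises(ValueError):
            gsea_preranked(ranked, _sets(S=["a"]), n_perm=5)


class TestORA:
    def test_zero_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(50)]
        res = ora(bg[:5], bg, _sets(S=bg[40:45]))
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_exact_tail_on_the_reference_configuration(self):
        bg = [f"g{i}" for i in range(100)]
        sets = _sets(S=bg[:10])       # K = 10
        sel = bg[:5] + bg[50:55]      # n = 10, k = 5
        res = ora(sel, bg, sets)
        assert res.iloc[0]["k"] == 5
        assert res.iloc[0]["p"] == pytest.approx(
            hypergeom_upper_tail(100, 10, 10, 5), abs=1e-12)

    def test_matches_exact_enumeration_on_random_configurations(self, rng):
        """200 random (N, K, n, k) cases agree with rational-arithmetic
        summation of the hypergeometric mass to 1e-10."""
        from scipy import stats as _unused  # noqa: F401

        for _ in range(200):
            N = int(rng.integers(10, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            bg = [f"g{i}" for i in range(N)]
            members = bg[:K]
            sel = bg[:k] + bg[K:K + (n - k)]
            if len(sel) != n:
                continue  # n - k exceeds the non-member pool
            res = ora(sel, bg, _sets(S=members))
            assert res.iloc[0]["p"] == pytest.approx(
                hypergeom_upper_tail(N, K, n, k), abs=1e-10)

    def test_monotone_in_overlap(self):
        N, K, n = 80, 15, 20
        bg = [f"g{i}" for i in range(N)]
        last = 1.1
        for k in range(0, min(K, n) + 1):
            sel = bg[:k] + bg[K:K + (n - k)]
            p = ora(sel, bg, _sets(S=bg[:K])).iloc[0]["p"]
            assert p <= last + 1e-12
            last = p

    def test_saturated_case_gives_p_one(self):
        bg = ["a", "b", "c", "d"]
        res = ora(bg, bg, _sets(S=bg))
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_selection_outside_background_errors(self):
        with pytest.raises(DataError):
            ora(["x"], ["a", "b"], _sets(S=["a"]))


class TestTopCorrelates:
    def test_selection_by_absolute_coefficient(self):
        tab = _table([("liver", "a", 0.2, 50, 0.1, 0.1),
                      ("liver", "b", -0.9, 50, 0.1, 0.1),
                      ("liver", "c", 0.5, 50, 0.1, 0.1)])
        selected, background = top_correlates(tab, "liver", top_n=2)
        assert selected == ["b", "c"]
        assert set(background) == {"a", "b", "c"}
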