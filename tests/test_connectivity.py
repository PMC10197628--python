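import numpy as np
import pandas as pd
import pytest

from pantissue import (
    DataError,
    PlantedPathway,
    SimulationConfig,
    TissueSpec,
    bicor,
    correlation_p,
    cross_tissue_counts,
    random_gene_null,
    simulate_archive,
    sparsity_diagnostic,
    tissue_ranking,
)
from conftest import make_tensor
from oracles import count_significant_pairs


@pytest.fixture(scope="module")
def small_archive():
    rng = np.random.default_rng(99)
    n = 40
    z = rng.normal(size=n)
    mats = {}
    for t in ("liver", "adipose", "muscle"):
        m = rng.normal(size=(15, n))
        # first 5 genes share a latent factor -> cross-tissue correlation
        m[:5] = 0.8 * z + 0.6 * rng.normal(size=(5, n))
        mats[t] = m
    return make_tensor(mats)


class TestCrossTissueCounts:
    @pytest.mark.parametrize("alpha", [1e-2, 1e-4])
    @pytest.mark.parametrize("mode", ["pairs", "genes"])
    def test_matches_brute_force_enumeration(self, small_archive, alpha, mode):
        genes = [f"g{i}" for i in range(15)]
        grids = cross_tissue_counts(
            small_archive, genes, thresholds=(alpha,), mode=mode,
            include_within=True, min_n=10)
        grid = grids[0].grid
        tissues = list(grid.index)
        for i, t1 in enumerate(tissues):
            for t2 in tissues[i:]:
                m1 = small_archive.matrix(t1).to_numpy()
                m2 = small_archive.matrix(t2).to_numpy()
                pairs, nodes = count_significant_pairs(
                    m1, m2, alpha, t1 == t2,
                    lambda a, b: bicor(a, b, min_n=10), correlation_p)
                expected = pairs if mode == "pairs" else len(nodes)
                assert grid.loc[t1, t2] == expected

    def test_within_tissue_cells_omitted_by_default(self, small_archive):
        genes = [f"g{i}" for i in range(10)]
        grid = cross_tissue_counts(small_archive, genes,
                                   thresholds=(0.01,))[0].grid
        assert np.isnan(np.diag(grid.to_numpy())).all()
        off = grid.to_numpy()[np.triu_indices(3, k=1)]
        assert np.isfinite(off).all()

    def test_stricter_threshold_never_increases_counts(self, small_archive):
        genes = [f"g{i}" for i in range(15)]
        loose, strict = cross_tissue_counts(
            small_archive, genes, thresholds=(1e-2, 1e-5),
            include_within=True)
        l, s = loose.grid.to_numpy(), strict.grid.to_numpy()
        assert (s[np.isfinite(s)] <= l[np.isfinite(l)]).all()

    def test_grid_is_symmetric(self, small_archive):
        genes = [f"g{i}" for i in range(15)]
        grid = cross_tissue_counts(small_archive, genes, thresholds=(0.01,),
                                   include_within=True)[0].grid.to_numpy()
        assert np.array_equal(grid, grid.T)

    def test_normalization_divides_by_pathway_size(self, small_archive):
        genes = [f"g{i}" for i in range(10)]
        cm = cross_tissue_counts(small_archive, genes, thresholds=(0.01,))[0]
        norm = cm.normalized().to_numpy()
        raw = cm.grid.to_numpy()
        mask = np.isfinite(raw)
        assert norm[mask] == pytest.approx(raw[mask] / 10)

    def test_empty_intersection_errors(self, small_archive):
        with pytest.raises(DataError):
            cross_tissue_counts(small_archive, ["nope1", "nope2"])


class TestTissueRanking:
    def test_planted_latent_tissues_rank_by_gene_hits(self, small_archive):
        genes = [f"g{i}" for i in range(15)]
        ranking = tissue_ranking(small_archive, genes, threshold=1e-3)
        # every tissue carries 5 latent genes; each should find partners
        assert (ranking.counts >= 5).all()
        assert sorted(ranking.order) == ["adipose", "liver", "muscle"]


class TestRandomGeneNull:
    def test_planted_pathway_exceeds_null_95th_percentile(self):
        cfg = SimulationConfig(
            n_individuals=100,
            tissues=(TissueSpec("liver", 150), TissueSpec("adipose", 150),
                     TissueSpec("muscle", 150)),
            pathway=PlantedPathway("PW", genes_per_tissue=8, rho=0.7),
            seed=13,
        )
        tensor, _, _, truth = simulate_archive(cfg)
        genes = sorted({g for gs in truth.pathway_members.values() for g in gs})
        observed = cross_tissue_counts(tensor, genes,
                                       thresholds=(1e-3,))[0].total_cross_tissue()
        null = random_gene_null(tensor, size=len(genes), n_draws=50, seed=5,
                                thresholds=(1e-3,))
        q95 = null["total_cross_tissue"].quantile(0.95)
        assert observed > q95

    def test_null_archive_pathway_sits_inside_null_band(self):
        cfg = SimulationConfig(
            n_individuals=100,
            tissues=(TissueSpec("liver", 100), TissueSpec("adipose", 100)),
            seed=17,
        )
        tensor = simulate_archive(cfg)[0]
        genes = [f"G{i:04d}" for i in range(10)]  # arbitrary background genes
        observed = cross_tissue_counts(tensor, genes,
                                       thresholds=(1e-2,))[0].total_cross_tissue()
        null = random_gene_null(tensor, size=10, n_draws=50, seed=6,
                                thresholds=(1e-2,))
        lo, hi = null["total_cross_tissue"].quantile([0.025, 1.0])
        assert lo <= observed <= max(hi, observed if observed <= hi else -1)
        assert observed <= hi

    def test_seeded_draws_are_reproducible(self, small_archive):
        kw = dict(size=5, n_draws=3, seed=11, thresholds=(0.01,))
        n1 = random_gene_null(small_archive, **kw)
        n2 = random_gene_null(small_archive, **kw)
        pd.testing.assert_frame_equal(n1, n2)

    def test_oversized_draw_errors(self, small_archive):
        with pytest.raises(DataError):
            random_gene_null(small_archive, size=1000, n_draws=1, seed=0)


class TestSparsityDiagnostic:
    @staticmethod
    def _counts(tissues, pathways, values):
        return pd.DataFrame(values, index=tissues, columns=pathways)

    def test_no_missing_data_is_flagged_undefined(self, rng):
        tensor = make_tensor({f"t{i}": rng.normal(size=(5, 20))
                              for i in range(12)})
        counts = self._counts([f"t{i}" for i in range(12)], ["pw"],
                              [[12 - i] for i in range(12)])
        res = sparsity_diagnostic(tensor, counts, tertile="bottom")
        assert not res.defined

    def test_negative_relation_across_burdened_tissues(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        mats, vals = {}, []
        for i, t in enumerate(tissues):
            m = rng.normal(size=(8, 40))
            m[:, : 2 * i] = np.nan
            mats[t] = m
            vals.append([40 - 3 * i, 38 - 3 * i, 36 - 3 * i])
        tensor = make_tensor(mats)
        table = self._counts(tissues, ["a", "b", "c"], vals)
        res = sparsity_diagnostic(tensor, table, tertile="bottom")
        assert res.defined
        assert res.r < 0

    def test_shuffled_burden_shows_no_relation(self, rng):
        tissues = [f"t{i}" for i in range(12)]
        burdens = rng.permutation(12)
        mats, vals = {}, []
        for i, t in enumerate(tissues):
            m = rng.normal(size=(8, 40))
            m[:, : int(2 * burdens[i])] = np.nan  # burden decoupled from counts
            mats[t] = m
            vals.append([int(v) for v in rng.integers(10, 40, size=3)])
        tensor = make_tensor(mats)
        table = self._counts(tissues, ["a", "b", "c"], vals)
        ps = []
        for tertile in ("top", "middle", "bottom"):
            res = sparsity_diagnostic(tensor, table, tertile=tertile)
            if res.defined:
                ps.append(res.p)
        assert ps and min(ps) > 0.01  # no spurious strong relation

    def test_requires_four_tissues_in_tertile(self, rng):
        tensor = make_tensor({f"t{i}": rng.normal(size=(3, 15))
                              for i in range(3)})
        counts = self._counts([f"t{i}" for i in range(3)], ["pw"],
                              [[3], [2], [1]])
        with pytest.raises(DataError):
            sparsity_diagnostic(tensor, counts, tertile="bottom")
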