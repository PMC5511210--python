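import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

import neuronet as nn
from neuronet import coexpression
from neuronet.preprocess import PipelineError


def _expr_from_array(Y):
    return nn.ExpressionMatrix(
        logcpm=pd.DataFrame(
            Y,
            index=[f"g{i:04d}" for i in range(Y.shape[0])],
            columns=[f"s{j}" for j in range(Y.shape[1])],
        )
    )


def _network(dataset, beta=9):
    cm, meta, _, _ = dataset
    corr = nn.residualize(nn.log_cpm(nn.filter_low_expression(cm)), meta)
    net = nn.tom_matrix(nn.adjacency_matrix(corr, beta=beta))
    return corr, net


class TestAdjacency:
    def test_powered_correlation_value(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        noise = rng.standard_normal(200)
        # construct a pair with correlation exactly -0.5 in sample terms
        y = -x.copy()
        Y = np.vstack([x, y])
        net = nn.adjacency_matrix(_expr_from_array(Y), beta=9)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        # analytic case: |cor| = 0.5 -> 0.5 ** 9
        assert 0.5**9 == pytest.approx(0.001953125)

    def test_perfectly_correlated_pair_unit_adjacency(self):
        Y = np.vstack([np.arange(10.0), 2 * np.arange(10.0) + 3])
        for beta in (1, 5, 9):
            net = nn.adjacency_matrix(_expr_from_array(Y), beta=beta)
            assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_invariant_under_joint_sample_permutation(self, rng):
        Y = rng.standard_normal((20, 15))
        a1 = nn.adjacency_matrix(_expr_from_array(Y), beta=6).adjacency
        perm = rng.permutation(15)
        a2 = nn.adjacency_matrix(_expr_from_array(Y[:, perm]), beta=6).adjacency
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_zero_variance_gene_rejected(self, rng):
        Y = rng.standard_normal((5, 10))
        Y[2] = 3.0
        with pytest.raises(PipelineError, match="g0002"):
            nn.adjacency_matrix(_expr_from_array(Y), beta=9)

    def test_signed_option_maps_to_unit_interval(self, rng):
        Y = rng.standard_normal((10, 12))
        net = nn.adjacency_matrix(_expr_from_array(Y), beta=4, signed=True)
        assert net.adjacency.min() >= 0 and net.adjacency.max() <= 1


class TestTom:
    @staticmethod
    def _tom_from_adjacency(a, beta=9):
        net = coexpression.NetworkModel(
            adjacency=a,
            connectivity=a.sum(axis=1) - 1,
            beta=beta,
            gene_ids=[f"g{i}" for i in range(a.shape[0])],
        )
        return nn.tom_matrix(net).tom

    def test_clique_tom_is_one(self):
        a = np.ones((5, 5))
        tom = self._tom_from_adjacency(a)
        np.testing.assert_allclose(tom, 1.0)

    def test_star_graph_leaf_leaf_tom_half(self):
        n = 6
        a = np.zeros((n, n))
        a[0, 1:] = a[1:, 0] = 1.0
        np.fill_diagonal(a, 1.0)
        tom = self._tom_from_adjacency(a)
        # leaves share exactly the hub: (1 + 0) / (1 + 1 - 0) = 0.5
        leaf_pairs = tom[1:, 1:][~np.eye(n - 1, dtype=bool)]
        np.testing.assert_allclose(leaf_pairs, 0.5)

    def test_random_adjacency_bounds_and_symmetry(self, rng):
        for _ in range(20):
            n = rng.integers(4, 30)
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = self._tom_from_adjacency(a)
            assert tom.min() >= 0.0 and tom.max() <= 1.0
            np.testing.assert_allclose(tom, tom.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(tom), 1.0)


class TestScaleFreeFit:
    def test_preferential_attachment_degree_law(self):
        import networkx as netx

        g = netx.barabasi_albert_graph(2000, 2, seed=1)
        k = np.array([d for _, d in g.degree()], dtype=float)
        r2, slope = nn.scale_free_fit(k, n_bins=10)
        assert r2 >= 0.8
        assert slope < 0

    def test_independent_genes_connectivity_decreases_with_power(self, rng):
        Y = rng.standard_normal((120, 20))
        res = nn.pick_soft_threshold(_expr_from_array(Y), powers=range(1, 10))
        mc = res.table["mean_connectivity"].to_numpy()
        assert (np.diff(mc) < 0).all()

    def test_no_spread_is_error(self):
        with pytest.raises(PipelineError, match="spread"):
            nn.scale_free_fit(np.full(50, 3.0))


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        cfg = nn.SimulationConfig(
            n_genes=200,
            module_spec=[nn.ModuleSpec(100, 0.7), nn.ModuleSpec(100, 0.7)],
            seed=2,
        )
        cm, meta, _, truth = nn.simulate_dataset(cfg)
        corr = nn.residualize(nn.log_cpm(cm), meta)
        net = nn.tom_matrix(nn.adjacency_matrix(corr, beta=9))
        a = nn.cut_modules(net)
        assert len(a.modules) == 2
        true = np.array([truth.module_of_gene[g] for g in corr.gene_ids])
        ari = adjusted_rand_score(true, a.module_of_gene.to_numpy())
        assert ari >= 0.95

    def test_fewer_genes_than_min_size_all_grey(self, rng):
        Y = rng.standard_normal((20, 15))
        net = nn.tom_matrix(nn.adjacency_matrix(_expr_from_array(Y), beta=9))
        a = nn.cut_modules(net, min_module_size=30)
        assert a.modules == []
        assert (a.module_of_gene == "grey").all()

    def test_null_data_stays_grey(self, null_dataset):
        corr, net = _network(null_dataset)
        a = nn.cut_modules(net)
        assert (a.module_of_gene == "grey").mean() > 0.9

    def test_module_sizes_respect_minimum(self, small_dataset):
        corr, net = _network(small_dataset)
        a = nn.cut_modules(net, min_module_size=30)
        for m in a.modules:
            assert a.module_sizes[m] >= 30

    def test_deterministic(self, small_dataset):
        corr, net = _network(small_dataset)
        a1 = nn.cut_modules(net)
        a2 = nn.cut_modules(net)
        pd.testing.assert_series_equal(a1.module_of_gene, a2.module_of_gene)

    def test_static_cut_height_mode(self, small_dataset):
        corr, net = _network(small_dataset)
        a = nn.cut_modules(net, cut_height=0.995)
        for m in a.modules:
            assert a.module_sizes[m] >= 30

    def test_largest_module_named_turquoise(self, small_dataset):
        corr, net = _network(small_dataset)
        a = nn.cut_modules(net)
        if a.modules:
            largest = max(a.modules, key=lambda m: a.module_sizes[m])
            assert largest == "turquoise"


class TestEigengene:
    def test_identical_genes_rank_one(self):
        base = np.sin(np.linspace(0, 3, 18))
        Y = np.tile(base, (5, 1)) * np.array([1, 2, 3, 4, 5])[:, None]
        expr = _expr_from_array(Y)
        assignment = coexpression.ModuleAssignment(
            module_of_gene=pd.Series("turquoise", index=expr.gene_ids),
            kim=pd.Series(0.0, index=expr.gene_ids),
            hub_flag=pd.Series(False, index=expr.gene_ids),
            module_sizes={"turquoise": 5},
        )
        s = nn.module_eigengene(expr, assignment, "turquoise")
        assert s.variance_explained == pytest.approx(1.0)
        assert np.linalg.norm(s.eigengene) == pytest.approx(1.0)
        # aligned with the common profile
        assert np.corrcoef(s.eigengene, base)[0, 1] > 0.99

    def test_sign_convention_follows_module_mean(self, small_dataset):
        cm, meta, _, truth = small_dataset
        corr = nn.residualize(nn.log_cpm(cm), meta)
        net = nn.tom_matrix(nn.adjacency_matrix(corr, beta=9))
        a = nn.cut_modules(net)
        m = a.modules[0]
        s = nn.module_eigengene(corr, a, m)
        members = corr.logcpm.loc[a.members(m)]
        std = members.sub(members.mean(axis=1), axis=0).div(
            members.std(axis=1), axis=0
        )
        assert np.corrcoef(s.eigengene, std.mean(axis=0))[0, 1] >= 0

        flipped = nn.ExpressionMatrix(logcpm=-corr.logcpm)
        s2 = nn.module_eigengene(flipped, a, m)
        assert np.corrcoef(s.eigengene, s2.eigengene)[0, 1] == pytest.approx(-1.0)

    def test_eigengene_tracks_planted_factor(self, small_dataset):
        cm, meta, _, truth = small_dataset
        corr = nn.residualize(nn.log_cpm(cm), meta)
        members = truth.module_members(0)
        assignment = coexpression.ModuleAssignment(
            module_of_gene=pd.Series(
                ["turquoise" if g in set(members) else "grey" for g in corr.gene_ids],
                index=corr.gene_ids,
            ),
            kim=pd.Series(0.0, index=corr.gene_ids),
            hub_flag=pd.Series(False, index=corr.gene_ids),
            module_sizes={"turquoise": len(members)},
        )
        s = nn.module_eigengene(corr, assignment, "turquoise")
        module_mean = corr.logcpm.loc[members].mean(axis=0)
        assert np.corrcoef(s.eigengene, module_mean)[0, 1] >= 0.9


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = nn.kruskal_wallis(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert h == pytest.approx(2.4)
        h2, p_exact = nn.kruskal_wallis_exact(
            np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])
        )
        assert h2 == pytest.approx(2.4)
        assert p_exact == pytest.approx(1 / 3)

    def test_identical_groups_h_zero(self):
        h, p = nn.kruskal_wallis(np.array([1, 2, 1, 2.0]), np.array([0, 0, 1, 1]))
        assert h == pytest.approx(0.0)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            vals = rng.integers(0, 5, size=12).astype(float)
            groups = np.array([0] * 5 + [1] * 7)
            if len(np.unique(vals)) < 2:
                continue
            h, p = nn.kruskal_wallis(vals, groups)
            ref = scipy.stats.kruskal(vals[groups == 0], vals[groups == 1])
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nn.kruskal_wallis(np.array([1.0, 2.0]), np.array([0, 0]))

    def test_status_shifted_module_detected(self):
        """An eigengene shifted by ~1 latent sd separates case/control in
        most replicates (two-sample power at n=17+19)."""
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = nn.SimulationConfig(
                n_genes=150,
                module_spec=[nn.ModuleSpec(60, 0.6, status_shift=1.0)],
                seed=seed,
            )
            cm, meta, _, truth = nn.simulate_dataset(cfg)
            expr = nn.log_cpm(cm)
            members = truth.module_members(0)
            assignment = coexpression.ModuleAssignment(
                module_of_gene=pd.Series(
                    ["blue" if g in set(members) else "grey" for g in expr.gene_ids],
                    index=expr.gene_ids,
                ),
                kim=pd.Series(0.0, index=expr.gene_ids),
                hub_flag=pd.Series(False, index=expr.gene_ids),
                module_sizes={"blue": 60},
            )
            s = nn.module_eigengene(expr, assignment, "blue")
            s = nn.eigengene_status_association(s, meta)
            hits += s.kw_pvalue < 0.05
        assert hits / n_rep >= 0.7


class TestHubs:
    @staticmethod
    def _assignment(sizes, kim_values=None):
        genes, colors = [], []
        for color, size in sizes.items():
            for i in range(size):
                genes.append(f"{color}{i:04d}")
                colors.append(color)
        kim = pd.Series(
            kim_values if kim_values is not None else np.arange(len(genes), dtype=float),
            index=genes,
        )
        return coexpression.ModuleAssignment(
            module_of_gene=pd.Series(colors, index=genes),
            kim=kim,
            hub_flag=pd.Series(False, index=genes),
            module_sizes=sizes,
        )

    @pytest.mark.parametrize("size,expected", [(50, 5), (550, 55), (31, 4)])
    def test_hub_count_is_ceil_ten_percent(self, size, expected):
        a = self._assignment({"blue": size})
        a = nn.find_hubs(a)
        assert a.hub_flag.sum() == expected

    def test_ties_broken_by_gene_id(self):
        a = self._assignment({"blue": 50}, kim_values=np.ones(50))
        a = nn.find_hubs(a)
        assert list(a.module_of_gene.index[a.hub_flag]) == [
            f"blue{i:04d}" for i in range(5)
        ]

    def test_hubs_have_top_connectivity(self, small_dataset):
        corr, net = _network(small_dataset)
        a = nn.cut_modules(net)
        for m in a.modules:
            members = a.members(m)
            hubs = a.hubs(m)
            non_hub_max = a.kim[[g for g in members if g not in set(hubs)]].max()
            assert a.kim[hubs].min() >= non_hub_max - 1e-12


class TestRobustness:
    def test_planted_module_strong_random_weak(self):
        cfg = nn.SimulationConfig(
            n_genes=500, module_spec=[nn.ModuleSpec(150, 0.7)], seed=4
        )
        cm, meta, _, truth = nn.simulate_dataset(cfg)
        expr = nn.log_cpm(cm)
        genes = expr.gene_ids
        rng = np.random.default_rng(0)
        rand = set(np.array(genes)[rng.choice(len(genes), 150, replace=False)])
        planted = set(truth.module_members(0))

        def make(assigned, color):
            return coexpression.ModuleAssignment(
                module_of_gene=pd.Series(
                    [color if g in assigned else "grey" for g in genes], index=genes
                ),
                kim=pd.Series(0.0, index=genes),
                hub_flag=pd.Series(False, index=genes),
                module_sizes={color: len(assigned)},
            )

        z_planted = nn.module_robustness(
            expr, make(planted, "turquoise"), beta=9, n_splits=8, n_perm=50, seed=1
        )
        z_random = nn.module_robustness(
            expr, make(rand, "blue"), beta=9, n_splits=8, n_perm=50, seed=1
        )
        assert z_planted["turquoise"] > 10
        assert z_random["blue"] < 2

    def test_deterministic_given_seed(self, small_dataset):
        corr, net = _network(small_dataset)
        a = nn.cut_modules(net)
        z1 = nn.module_robustness(corr, a, beta=9, n_splits=3, n_perm=20, seed=9)
        z2 = nn.module_robustness(corr, a, beta=9, n_splits=3, n_perm=20, seed=9)
        assert z1 == z2


class TestEstimator:
    def test_sklearn_surface(self, small_dataset):
        cm, meta, _, _ = small_dataset
        corr = nn.residualize(nn.log_cpm(cm), meta)
        X = corr.logcpm.to_numpy().T
        est = nn.CoexpressionNetwork(beta=9, min_module_size=30)
        est.fit(X)
        assert est.labels_.shape == (X.shape[1],)
        assert set(est.labels_) >= {-1}
        assert est.get_params()["beta"] == 9
        params = est.get_params()
        est2 = nn.CoexpressionNetwork(**params).fit(X)
        np.testing.assert_array_equal(est.labels_, est2.labels_)
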