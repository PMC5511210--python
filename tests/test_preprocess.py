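import numpy as np
import pandas as pd
import pytest

import neuronet as nn
from neuronet.preprocess import (
    LowExpressionFilter,
    PipelineError,
    SurrogateVariableAnalysis,
    build_design,
)


def _make_counts(rows, samples=None):
    arr = np.asarray(rows)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return nn.CountMatrix.from_counts(pd.DataFrame(arr, index=genes, columns=samples))


class TestFilterLowExpression:
    def test_rule_membership_on_forced_example(self):
        """Gene kept iff #samples with CPM < 1 is at most max_low_samples."""
        n = 12
        lib = 1_000_000
        # per-sample library ~1e6 dominated by a ballast gene
        low = 0  # CPM 0 < 1
        high = 10  # CPM 10 >= 1
        rows = {
            "A": [high] * n,                      # low in 0 samples -> keep
            "B": [low] * 10 + [high] * 2,         # low in exactly 10 -> keep
            "C": [low] * 11 + [high],             # low in 11 -> drop
            "D": [low] * n,                       # low in all -> drop
            "ballast": [lib] * n,
        }
        counts = pd.DataFrame(rows).T
        counts.columns = [f"s{j}" for j in range(n)]
        cm = nn.CountMatrix.from_counts(counts)
        kept = nn.filter_low_expression(cm, cpm_threshold=1.0, max_low_samples=10)
        assert set(kept.gene_ids) == {"A", "B", "ballast"}

    def test_vacuous_threshold_keeps_everything(self, toy_counts):
        kept = nn.filter_low_expression(toy_counts, max_low_samples=2)
        assert kept.gene_ids == toy_counts.gene_ids

    def test_all_zero_gene_removed(self):
        cm = _make_counts([[0] * 12, [100] * 12])
        kept = nn.filter_low_expression(cm, max_low_samples=10)
        assert kept.gene_ids == ["g1"]

    def test_idempotent_and_preserves_library_size(self, small_dataset):
        cm = small_dataset[0]
        once = nn.filter_low_expression(cm)
        twice = nn.filter_low_expression(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        pd.testing.assert_series_equal(once.library_size, cm.library_size)

    def test_everything_removed_is_fatal(self):
        counts = pd.DataFrame([[0] * 12], index=["g0"],
                              columns=[f"s{j}" for j in range(12)])
        cm = nn.CountMatrix(
            counts=counts, library_size=pd.Series(1_000_000, index=counts.columns)
        )
        with pytest.raises(PipelineError, match="threshold"):
            nn.filter_low_expression(cm)

    def test_estimator_surface(self, small_dataset):
        X = small_dataset[0].counts.to_numpy().T
        est = LowExpressionFilter().fit(X)
        assert est.transform(X).shape[1] == est.get_support().sum()
        assert est.get_params()["cpm_threshold"] == 1.0


class TestLogCpm:
    def test_formula_values(self):
        cm = _make_counts([[0], [999], [999_000]])
        cm.library_size[:] = 1_000_000
        vals = nn.log_cpm(cm, prior_count=0.5).logcpm["s0"]
        assert vals["g0"] == pytest.approx(np.log2(0.5 / 1_000_001 * 1e6), abs=1e-9)
        assert vals["g0"] == pytest.approx(-1.0000014, abs=1e-4)
        assert vals["g1"] == pytest.approx(np.log2(999.5 / 1_000_001 * 1e6), abs=1e-9)
        assert vals["g1"] == pytest.approx(9.9656, abs=2e-3)

    def test_monotone_in_count(self, rng):
        counts = np.sort(rng.integers(0, 1000, size=50))
        cm = _make_counts(counts[:, None])
        vals = nn.log_cpm(cm).logcpm["s0"].to_numpy()
        assert (np.diff(vals) >= 0).all()

    def test_scale_invariance_limit(self):
        cm1 = _make_counts([[10_000], [500_000]])
        cm2 = _make_counts([[20_000], [1_000_000]])
        d = nn.log_cpm(cm1).logcpm.to_numpy() - nn.log_cpm(cm2).logcpm.to_numpy()
        assert np.abs(d).max() < 1e-4


class TestScreenCovariates:
    def test_midpoint_grid_ks_statistic(self):
        """KS distance of the exact uniform mid-point grid is 0.5/m."""
        import scipy.stats

        m = 200
        grid = (np.arange(1, m + 1) - 0.5) / m
        stat = scipy.stats.kstest(grid, "uniform").statistic
        assert stat == pytest.approx(0.5 / m, abs=1e-12)

    def test_planted_covariate_declared_widespread(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = nn.SimulationConfig(
                n_genes=800,
                seed=seed,
                covariate_effects={"rin": nn.CovariateEffect(0.5, 1.0)},
            )
            cm, meta, _, _ = nn.simulate_dataset(cfg)
            res = nn.screen_covariates(nn.log_cpm(cm), meta, alpha=0.01)
            hits += res.widespread["rin"]
        assert hits == n_rep

    def test_null_generator_covariates_not_widespread(self):
        """Without planted effects every covariate's p-values stay uniform."""
        false_calls, total = 0, 0
        for seed in range(10):
            cfg = nn.SimulationConfig(n_genes=800, seed=100 + seed)
            cm, meta, _, _ = nn.simulate_dataset(cfg)
            res = nn.screen_covariates(nn.log_cpm(cm), meta, alpha=0.01)
            false_calls += sum(res.widespread.values())
            total += len(res.widespread)
        assert false_calls / total <= 0.05

    def test_constant_covariate_excluded(self, small_dataset):
        cm, meta, _, _ = small_dataset
        meta = meta.copy()
        meta["pmi"] = 10.0
        res = nn.screen_covariates(nn.log_cpm(cm), meta)
        assert "pmi" not in res.ks_statistic
        assert "rin" in res.ks_statistic


class TestVarianceFractions:
    def test_gene_equal_to_covariate_fully_attributed(self, small_dataset):
        cm, meta, _, _ = small_dataset
        expr = nn.log_cpm(nn.filter_low_expression(cm))
        rin = (meta["rin"] - meta["rin"].mean()) / meta["rin"].std(ddof=0)
        expr.logcpm.iloc[0] = rin.to_numpy()
        res = nn.variance_fractions(expr, meta)
        row = res.variance_fraction.iloc[0]
        assert row["rin"] == pytest.approx(1.0, abs=1e-6)
        assert row["residual"] == pytest.approx(0.0, abs=1e-6)

    def test_fractions_sum_to_one(self, small_dataset):
        cm, meta, _, _ = small_dataset
        res = nn.variance_fractions(nn.log_cpm(cm), meta)
        sums = res.variance_fraction.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_null_fraction_matches_df_expectation(self, rng):
        """Pure-noise genes: each single-df covariate explains ~1/(n-1)."""
        n, g = 36, 2000
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "status": ["control"] * 18 + ["case"] * 18,
                "rin": rng.normal(3, 0.5, n),
                "pmi": rng.normal(15, 4, n).clip(1),
                "age": rng.normal(35, 8, n).clip(18),
                "race": rng.choice(["AA", "H", "C"], n),
            }
        )
        Y = rng.standard_normal((g, n))
        expr = nn.ExpressionMatrix(
            logcpm=pd.DataFrame(Y, index=[f"g{i}" for i in range(g)],
                                columns=meta["sample_id"])
        )
        res = nn.variance_fractions(expr, meta)
        for cov in ("rin", "pmi", "age"):
            assert res.variance_fraction[cov].mean() == pytest.approx(
                1 / (n - 1), abs=0.02
            )
        # race has 2 dummy df
        assert res.variance_fraction["race"].mean() == pytest.approx(
            2 / (n - 1), abs=0.02
        )

    def test_invariant_to_affine_covariate_rescaling(self, small_dataset):
        cm, meta, _, _ = small_dataset
        expr = nn.log_cpm(cm)
        a = nn.variance_fractions(expr, meta).variance_fraction
        meta2 = meta.copy()
        meta2["rin"] = meta2["rin"] * 10 + 3
        b = nn.variance_fractions(expr, meta2).variance_fraction
        pd.testing.assert_frame_equal(a, b, atol=1e-9, rtol=0)

    def test_collinear_design_fatal(self, small_dataset):
        cm, meta, _, _ = small_dataset
        meta = meta.copy()
        meta["rin2"] = meta["rin"]
        with pytest.raises(PipelineError, match="collinear"):
            nn.variance_fractions(
                nn.log_cpm(cm), meta, covariates=("rin", "rin2", "pmi")
            )


class TestSurrogateVariables:
    @staticmethod
    def _noise_expr(rng, n_genes=500, n=36):
        Y = rng.standard_normal((n_genes, n))
        return nn.ExpressionMatrix(
            logcpm=pd.DataFrame(
                Y, index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(n)],
            )
        )

    @staticmethod
    def _design(n=36):
        return pd.DataFrame({"intercept": np.ones(n)}, index=[f"s{j}" for j in range(n)])

    def test_pure_noise_rarely_finds_svs(self, rng):
        zero = 0
        for seed in range(10):
            expr = self._noise_expr(np.random.default_rng(seed))
            sv = nn.estimate_surrogate_variables(
                expr, self._design(), n_perm=50, seed=seed
            )
            zero += sv.n_sv == 0
        assert zero >= 9

    def test_hidden_batch_recovered(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            expr = self._noise_expr(rng)
            batch = np.zeros(36)
            batch[rng.choice(36, 18, replace=False)] = 1.0
            affected = rng.choice(500, 150, replace=False)
            Y = expr.logcpm.to_numpy()
            Y[affected] += np.outer(np.ones(150), batch)
            sv = nn.estimate_surrogate_variables(
                expr, self._design(), n_perm=50, seed=seed
            )
            if sv.n_sv >= 1:
                c = abs(np.corrcoef(sv.sv_matrix.iloc[:, 0], batch)[0, 1])
                hits += c > 0.8
        assert hits >= 9

    def test_deterministic_and_orthogonal(self, small_dataset):
        cm, meta, _, _ = small_dataset
        expr = nn.log_cpm(cm)
        design = build_design(meta)
        a = nn.estimate_surrogate_variables(expr, design, n_perm=30, seed=5)
        b = nn.estimate_surrogate_variables(expr, design, n_perm=30, seed=5)
        pd.testing.assert_frame_equal(a.sv_matrix, b.sv_matrix)
        if a.n_sv > 1:
            gram = a.sv_matrix.to_numpy().T @ a.sv_matrix.to_numpy()
            assert np.allclose(gram, np.eye(a.n_sv), atol=1e-8)

    def test_svs_orthogonal_to_design(self, small_dataset):
        """Surrogate variables cannot absorb the protected status effect."""
        cm, meta, _, _ = small_dataset
        expr = nn.log_cpm(cm)
        design = build_design(meta)
        sv = nn.estimate_surrogate_variables(expr, design, n_perm=30, seed=5)
        if sv.n_sv:
            proj = design.to_numpy().T @ sv.sv_matrix.to_numpy()
            assert np.abs(proj).max() < 1e-8

    def test_estimator_fit_transform(self, rng):
        est = SurrogateVariableAnalysis(n_perm=30, random_state=0)
        X = rng.standard_normal((20, 100))
        out = est.fit_transform(X)
        assert out.shape[0] == 20
        assert est.n_sv_ == out.shape[1]


class TestTmm:
    def test_balanced_data_factors_near_one(self, small_dataset):
        from neuronet.preprocess import tmm_factors

        f = tmm_factors(small_dataset[0])
        assert np.allclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-9)
        assert f.between(0.8, 1.25).all()

    def test_composition_bias_corrected_direction(self, small_dataset):
        from neuronet.preprocess import tmm_factors

        cm = small_dataset[0]
        arr = cm.counts.to_numpy().copy()
        arr[: arr.shape[0] // 2, :10] *= 4
        biased = nn.CountMatrix.from_counts(
            pd.DataFrame(arr, index=cm.gene_ids, columns=cm.sample_ids)
        )
        f = tmm_factors(biased)
        # inflated samples get factors < 1 so unaffected genes regain scale
        assert f.iloc[:10].mean() < f.iloc[10:].mean()

    def test_log_cpm_tmm_option(self, small_dataset):
        a = nn.log_cpm(small_dataset[0])
        b = nn.log_cpm(small_dataset[0], normalize="tmm")
        assert a.logcpm.shape == b.logcpm.shape
        assert not np.allclose(a.logcpm, b.logcpm)
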