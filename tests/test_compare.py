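import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollenselect import compare as cmp


class TestMannWhitney:
    def test_identical_constant_groups(self):
        U, raw, adj = cmp.mann_whitney_bonferroni([2, 2, 2], [2, 2, 2], 3)
        assert raw == 1.0 and adj == 1.0

    def test_exact_enumeration_value(self):
        """Full separation of 3 vs 3: 2 of the C(6,3)=20 rank arrangements
        are as extreme, so the exact two-sided p is 0.1."""
        U, raw, adj = cmp.mann_whitney_bonferroni([1, 2, 3], [10, 11, 12])
        assert U == 0.0
        assert raw == pytest.approx(0.1)

    def test_bonferroni_multiplication(self):
        assert cmp.bonferroni(0.03, 6) == pytest.approx(0.18)
        assert cmp.bonferroni(0.5, 6) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            cmp.mann_whitney_bonferroni([], [1.0])


class TestPartialSpearman:
    def test_perfect_dependence_with_noise_control(self, rng):
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        rho, p = cmp.partial_spearman(x, x + 0.0, controls=z)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_null_independence(self, rng):
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        z = rng.normal(size=500)
        rho, p = cmp.partial_spearman(x, y, controls=z)
        assert abs(rho) < 0.1

    def test_matrix_identity_oracle(self, rng):
        """Residual-based partial correlation equals the inverse-
        correlation-matrix formula on a 5-variable fixture."""
        n = 120
        base = rng.normal(size=(n, 5))
        data = base @ rng.normal(size=(5, 5)) + 0.5 * rng.normal(size=(n, 5))
        ranks = np.column_stack([stats.rankdata(data[:, j]) for j in range(5)])
        R = np.corrcoef(ranks, rowvar=False)
        P = np.linalg.inv(R)
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        rho, _ = cmp.partial_spearman(data[:, 0], data[:, 1], controls=data[:, 2:])
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_constant_variable_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            cmp.partial_spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPCRegression:
    def test_single_predictor_equals_simple_regression(self, rng):
        x = np.exp(rng.normal(0, 0.5, 100))
        y = np.exp(1.3 * np.log(x) + rng.normal(0, 0.2, 100))
        model = cmp.pc_regression(pd.Series(y, name="y"), pd.DataFrame({"x": x}))
        x_log = np.log(x)
        y_log = np.log(y)
        slope_simple = np.cov(x_log, y_log)[0, 1] / np.var(x_log, ddof=1)
        # PC1 of one predictor is that predictor standardised
        slope_pcr = cmp._pcr_coefficients(y_log, pd.DataFrame({"x": x_log}))[0]
        assert slope_pcr * 1.0 / np.std(x_log, ddof=1) == pytest.approx(slope_simple, rel=1e-9)
        assert model.predictors == ["x"]

    def test_irrelevant_orthogonal_predictor_pruned(self, rng):
        x1 = np.exp(rng.normal(0, 0.5, 300))
        x2 = np.exp(rng.normal(0, 0.5, 300))
        y = np.exp(0.8 * np.log(x1) + rng.normal(0, 0.3, 300))
        model = cmp.pc_regression(
            pd.Series(y, name="y"), pd.DataFrame({"signal": x1, "noise": x2})
        )
        assert model.predictors == ["signal"]
        assert any("noise" in h["predictors"] for h in model.pruning_history)

    def test_explained_pct_is_squared_correlation(self, rng):
        x1 = np.exp(rng.normal(0, 0.5, 150))
        x2 = np.exp(rng.normal(0, 0.5, 150))
        y = np.exp(0.5 * np.log(x1) - 0.4 * np.log(x2) + rng.normal(0, 0.3, 150))
        X = pd.DataFrame({"a": x1, "b": x2})
        model = cmp.pc_regression(pd.Series(y, name="y"), X, alpha=1.1)  # no pruning
        # oracle: correlate the dependent with each component score directly
        X_log = np.log(X)
        Xs = (X_log - X_log.mean()) / X_log.std(ddof=1)
        _, _, Vt = np.linalg.svd(Xs.values, full_matrices=False)
        y_log = np.log(y)
        for j in range(2):
            score = Xs.values @ Vt[j]
            r2 = np.corrcoef(score, y_log)[0, 1] ** 2
            assert model.explained_pct[j] == pytest.approx(100 * r2, rel=1e-9)

    def test_zero_dependent_offset_recorded(self, rng):
        y = np.concatenate([[0.0, 0.0], np.exp(rng.normal(0, 1, 50))])
        x = np.exp(rng.normal(0, 1, 52))
        model = cmp.pc_regression(pd.Series(y, name="y"), pd.DataFrame({"x": x}), alpha=1.1)
        assert model.dependent_offset == pytest.approx(float(np.min(y[y > 0])) / 2)

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            cmp.pc_regression(pd.Series([1.0] * 5, name="y"), pd.DataFrame({"x": [1.0] * 5}))


class TestAncovaBins:
    def _shifted_groups(self, rng, shift=1.0, n=200):
        pc = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        labels = np.array(["a"] * n + ["b"] * n)
        y = -0.5 * pc + rng.normal(0, 0.3, 2 * n)
        y[labels == "a"] += shift
        return y, pc, labels

    def test_constant_shift_parallel_slopes(self, rng):
        y, pc, labels = self._shifted_groups(rng)
        res = cmp.ancova_with_bins(y, pc, labels)
        assert res.interaction_p > 0.05
        assert res.group_p < 1e-6
        assert res.slope_a == pytest.approx(res.slope_b, abs=0.15)
        assert all(b.adj_p < 0.05 for b in res.bins if b.tested)

    def test_identical_groups_nonsignificant(self, rng):
        y, pc, labels = self._shifted_groups(rng, shift=0.0)
        res = cmp.ancova_with_bins(y, pc, labels)
        assert res.adj_p > 0.05
        assert all(b.raw_p > 0.001 for b in res.bins if b.tested)

    def test_bins_equal_count(self, rng):
        y, pc, labels = self._shifted_groups(rng, n=103)
        res = cmp.ancova_with_bins(y, pc, labels, n_bins=5)
        sizes = [b.n_a + b.n_b for b in res.bins]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 206

    def test_empty_bin_group_untested(self, rng):
        pc = np.concatenate([np.linspace(-3, -1, 50), np.linspace(1, 3, 50)])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        y = pc + rng.normal(0, 0.1, 100)
        res = cmp.ancova_with_bins(y, pc, labels, n_bins=5)
        assert any(not b.tested for b in res.bins)


class TestNullCalibration:
    def test_group_test_rejects_at_nominal_rate(self):
        """With identical generative parameters for both classes the
        Mann-Whitney rejection rate stays near nominal over 50 seeds."""
        from dataclasses import replace

        from pollenselect import synthetic_data as sd
        from pollenselect import diversity as dv

        cfg0 = sd.null_config(
            seed=0, n_chromosomes=1, genes_per_chromosome=40, n_strains=24,
            low_quality_rate=0.0,
        )
        genome, models, truth = sd.simulate_genome(cfg0)
        class_of = dict(zip(truth["gene_id"], truth["life_stage_class"]))
        pvals = []
        for seed in range(50):
            cfg = replace(cfg0, seed=seed + 1)
            records, strains = sd.simulate_strain_variants(cfg, genome, models, truth)
            df, _ = dv.diversity_table(models, genome, records, strains)
            df["cls"] = df["gene_id"].map(class_of)
            a = df.loc[df["cls"] == "pollen_specific", "theta_n"]
            b = df.loc[df["cls"] == "sporophyte_specific", "theta_n"]
            _, raw, _ = cmp.mann_whitney_bonferroni(a, b)
            pvals.append(raw)
        pvals = np.asarray(pvals)
        # 50 null replicates: at alpha=0.01 expect 0.5 rejections
        assert (pvals < 0.01).sum() <= 3
        # and the p distribution should not be grossly non-uniform
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3
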