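from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm

from qrgwas.scan import (LinearGWAS, QuantileGWAS, ScanConfig, check_loss,
                         fit_ols_model, fit_quantile_model,
                         qr_rank_score_test, qvalues, scan)


def exhaustive_qr_objective(y, X, tau):
    """Minimum check loss over all exact-fit bases (LP vertex oracle)."""
    n, p = X.shape
    best = np.inf
    for S in combinations(range(n), p):
        XS = X[list(S)]
        if abs(np.linalg.det(XS)) < 1e-12:
            continue
        theta = np.linalg.solve(XS, y[list(S)])
        best = min(best, check_loss(y - X @ theta, tau).sum())
    return best


class TestCheckLoss:
    @pytest.mark.parametrize("tau, eps, expected", [
        (0.5, 2.0, 1.0), (0.5, -2.0, 1.0),
        (0.9, 2.0, 1.8), (0.9, -2.0, 0.2),
        (0.1, 0.0, 0.0), (0.7, 0.0, 0.0),
    ])
    def test_piecewise_definition(self, tau, eps, expected):
        assert check_loss(eps, tau) == pytest.approx(expected)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.2])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(ValueError):
            check_loss(1.0, tau)


class TestFitQuantileModel:
    def test_intercept_only_median(self):
        f = fit_quantile_model(np.array([1.0, 2.0, 9.0]), np.ones((3, 1)), 0.5)
        assert f.params[0] == pytest.approx(2.0)

    def test_intercept_only_upper_quantile(self):
        y = np.arange(10.0)
        f = fit_quantile_model(y, np.ones((10, 1)), 0.9)
        # any LP-optimal value is accepted: check the objective instead
        cand = min(check_loss(y - v, 0.9).sum() for v in y)
        assert f.objective == pytest.approx(cand, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_matches_exhaustive_vertex_oracle(self, seed, tau):
        rng = np.random.default_rng(seed)
        n, p = 8, 2
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = rng.standard_normal(n)
        f = fit_quantile_model(y, X, tau)
        assert f.objective == pytest.approx(
            exhaustive_qr_objective(y, X, tau), abs=1e-8)

    def test_residual_sign_count_optimality_bounds(self):
        """At an optimum: #(resid < 0) <= n·tau <= #(resid <= 0)."""
        rng = np.random.default_rng(5)
        for tau in (0.25, 0.5, 0.75):
            X = np.column_stack([np.ones(60), rng.standard_normal((60, 2))])
            y = rng.standard_normal(60)
            f = fit_quantile_model(y, X, tau)
            neg = np.sum(f.residuals < -1e-9)
            zero = np.sum(np.abs(f.residuals) <= 1e-9)
            assert neg <= 60 * tau + 1e-9
            assert 60 * tau <= neg + zero + 1e-9

    def test_median_fit_beats_ols_on_lad_objective(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(80), rng.standard_normal((80, 3))])
        y = X @ np.array([1.0, 2.0, 0.0, -1.0]) + rng.standard_normal(80) ** 3
        f = fit_quantile_model(y, X, 0.5)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert f.objective <= check_loss(y - X @ beta_ols, 0.5).sum() + 1e-9

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_quantile_model(np.arange(10.0), X, 0.5)

    def test_agrees_with_statsmodels_quantreg(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        y = X @ np.array([0.5, 1.0, -2.0]) + rng.standard_normal(200)
        for tau in (0.1, 0.5, 0.9):
            ours = fit_quantile_model(y, X, tau)
            ref = sm.QuantReg(y, X).fit(q=tau)
            ref_obj = check_loss(y - X @ ref.params, tau).sum()
            assert ours.objective <= ref_obj + 1e-6


class TestRankScoreTest:
    def test_type_one_error_nominal(self):
        """Null markers at n=500: rejection at 0.05 within binomial 99% CI."""
        rng = np.random.default_rng(8)
        n, m = 500, 2000
        y = rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        p, _ = qr_rank_score_test(y, Z, X, 0.5)
        rate = np.mean(p < 0.05)
        half = 2.576 * np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < half

    def test_power_on_strong_effect(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.integers(0, 3, n).astype(float)
        y = x * 1.0 + rng.standard_normal(n)     # ≥ 1 phenotypic SD effect
        p, _ = qr_rank_score_test(y, np.ones((n, 1)), x, 0.5)
        assert p < 1e-6

    def test_collinear_marker_rejected(self):
        rng = np.random.default_rng(10)
        n = 50
        z = rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), z])
        with pytest.raises(np.linalg.LinAlgError):
            qr_rank_score_test(rng.standard_normal(n), Z, z.copy(), 0.5)

    def test_rank_scores_orthogonal_to_design(self):
        rng = np.random.default_rng(11)
        n = 300
        Z = np.column_stack([np.ones(n), rng.standard_normal((n, 4))])
        f = fit_quantile_model(rng.standard_normal(n), Z, 0.25)
        assert np.max(np.abs(Z.T @ f.rank_scores)) < 1e-8
        assert f.rank_scores.min() >= 0.25 - 1 - 1e-8
        assert f.rank_scores.max() <= 0.25 + 1e-8


class TestOLS:
    def test_exact_fit(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        params, pval, res = fit_ols_model(2.0 * x, X)
        assert params[1] == pytest.approx(2.0)
        assert res.ssr == pytest.approx(0.0, abs=1e-18)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        y = rng.standard_normal(50)
        params, _, _ = fit_ols_model(y, X)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(params, oracle, atol=1e-10)

    def test_type_one_error_nominal(self):
        rng = np.random.default_rng(13)
        n, m = 400, 2000
        y = rng.standard_normal(n)
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        res = LinearGWAS(y, X).fit()
        rate = np.mean(res.table["pvalue"] < 0.05)
        half = 2.576 * np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < half

    def test_rank_deficiency_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols_model(np.arange(4.0), np.ones((4, 2)))


class TestQValues:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(qvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(qvalues([0.17]), [0.17])

    def test_monotone_and_matches_step_up_oracle(self):
        rng = np.random.default_rng(14)
        p = rng.random(200)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # first-principles BH: cumulative minimum of p_(j)·m/j from the top
        m = p.size
        ranked = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        np.testing.assert_allclose(q[order], oracle, atol=1e-12)
        assert np.all(q >= p - 1e-12)         # adjustment never shrinks p
        assert np.all((q >= 0) & (q <= 1))

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(15)
        p = rng.random(500)
        assert np.all(qvalues(p, method="storey") <= qvalues(p) + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.5])


class TestScanConfig:
    def test_qr_requires_tau(self):
        with pytest.raises(ValueError):
            ScanConfig(method="QR")
        with pytest.raises(ValueError):
            ScanConfig(method="QR", tau=1.0)
        assert ScanConfig(method="QR", tau=0.1).label == "QR(0.10)"

    def test_alpha_range(self):
        with pytest.raises(ValueError):
            ScanConfig(method="GLM", alpha=0.0)


class TestScanLevel:
    def test_null_scan_finds_almost_nothing(self, default_cohort,
                                            default_structure):
        _, cohort, _ = default_cohort
        _, cov = default_structure
        y = np.random.default_rng(16).standard_normal(cohort.n)
        res = scan(cohort, y, cov, ScanConfig(method="GLM"))
        assert res.n_significant <= 2

    def test_positive_control_detects_major_qtl(self, default_cohort,
                                                default_structure):
        """A huge-effect QTL (h²=0.9) is flagged by both methods nearby."""
        gmap, cohort, _ = default_cohort
        _, cov = default_structure
        q = 0                                       # first QTL as the signal
        dose = cohort.qtl_dosages[:, q].astype(float)
        rng = np.random.default_rng(17)
        y = dose + rng.normal(0, np.sqrt(np.var(dose) / 9), cohort.n)
        near = np.flatnonzero(
            (gmap.marker_chrom == gmap.qtl_chrom[q])
            & (np.abs(gmap.marker_pos - gmap.qtl_pos[q]) <= 0.5))
        for cfg in (ScanConfig(method="GLM"),
                    ScanConfig(method="QR", tau=0.5)):
            res = scan(cohort, y, cov, cfg)
            assert np.isin(near, res.significant_marker_idx).any(), cfg.label

    def test_glm_scan_matches_per_marker_ols_oracle(self, default_cohort,
                                                    default_structure):
        gmap, cohort, trait = default_cohort
        _, cov = default_structure
        res = scan(cohort, trait.phenotypes, cov, ScanConfig(method="GLM"))
        rng = np.random.default_rng(18)
        rows = rng.choice(len(res.table), 25, replace=False)
        X = cohort.marker_dosages.astype(float)
        for r in rows:
            j = int(res.table["marker_idx"].iloc[r])
            design = np.column_stack(
                [np.ones(cohort.n), X[:, j], cov.scores])
            _, pval, full = fit_ols_model(trait.phenotypes, design)
            assert res.table["pvalue"].iloc[r] == pytest.approx(pval, rel=1e-8)
            assert res.table["effect"].iloc[r] == pytest.approx(
                full.params[1], rel=1e-8)

    def test_marker_order_invariance(self, small_cohort):
        rng = np.random.default_rng(19)
        y = rng.standard_normal(small_cohort.n)
        X = small_cohort.marker_dosages.astype(float)
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        perm = rng.permutation(X.shape[1])
        a = LinearGWAS(y, X).fit()
        b = LinearGWAS(y, X[:, perm]).fit()
        pa = a.table["pvalue"].to_numpy()
        pb = b.table["pvalue"].to_numpy()
        # marker k of the permuted scan is original marker perm[k]
        np.testing.assert_allclose(pb, pa[perm], atol=1e-12)
        a = QuantileGWAS(y, X, tau=0.5).fit()
        b = QuantileGWAS(y, X[:, perm], tau=0.5).fit()
        np.testing.assert_allclose(b.table["pvalue"].to_numpy(),
                                   a.table["pvalue"].to_numpy()[perm],
                                   atol=1e-9)

    def test_monomorphic_markers_listed(self, small_map):
        from conftest import random_population
        pop = random_population(small_map, 60, seed=20)
        pop.haplotypes[:, :, 3] = 0
        y = np.random.default_rng(21).standard_normal(60)
        res = scan(pop, y, None, ScanConfig(method="GLM"))
        assert (res.skipped["reason"] == "monomorphic").all()
        assert len(res.table) + len(res.skipped) == small_map.n_markers

    def test_significant_iff_q_below_alpha(self, default_cohort,
                                           default_structure):
        _, cohort, trait = default_cohort
        _, cov = default_structure
        res = scan(cohort, trait.phenotypes, cov,
                   ScanConfig(method="QR", tau=0.5, alpha=0.2))
        np.testing.assert_array_equal(
            res.table["significant"], res.table["qvalue"] <= 0.2)

    def test_qr_effects_estimated_on_demand(self, small_cohort):
        rng = np.random.default_rng(22)
        X = small_cohort.marker_dosages.astype(float)
        keep = X.std(axis=0) > 0
        y = X[:, np.flatnonzero(keep)[0]] * 2 + rng.standard_normal(
            small_cohort.n) * 0.5
        res = QuantileGWAS(y, X[:, keep], tau=0.5).fit(alpha=0.05,
                                                       effects="significant")
        sig = res.table["significant"]
        assert sig.any()
        assert res.table.loc[sig, "effect"].notna().all()
        assert res.table.loc[~sig, "effect"].isna().all()

    def test_summary_mentions_key_counts(self, small_cohort):
        y = np.random.default_rng(23).standard_normal(small_cohort.n)
        X = small_cohort.marker_dosages.astype(float)
        res = LinearGWAS(y, X).fit()
        text = res.summary()
        assert "markers tested" in text and "significant" in text
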