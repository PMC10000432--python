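"""Mixed condition models: Box-Cox, REML fits, diagnostics, bootstrap."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

from caremod import mixed
from caremod.simulate import CONDITIONS, FeatureSimConfig, simulate_features


def _equal_means(value=0.5):
    return {c: value for c in CONDITIONS}


class TestSelectBoxcox:
    def test_lognormal_prefers_log(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.normal(0.0, 1.0, size=2000))
        lam = mixed.select_boxcox(y)
        assert -0.15 <= lam <= 0.15

    def test_gaussian_prefers_identity(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10.0, 1.0, size=2000)
        lam = mixed.select_boxcox(y)
        assert 0.6 <= lam <= 1.4

    def test_lambda_one_is_affine_shift(self):
        y = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(mixed.boxcox_transform(y, 1.0), y - 1.0)

    def test_nonpositive_without_shift_errors(self):
        with pytest.raises(ValueError):
            mixed.select_boxcox(np.array([-1.0, 2.0, 3.0]))

    def test_auto_shift_handles_nonpositive(self):
        y = np.array([-1.0, 0.5, 2.0, 3.0, 1.0, 0.2])
        lam = mixed.select_boxcox(y, shift=None)
        assert -2.0 <= lam <= 2.0

    def test_inverse_roundtrip(self):
        y = np.array([0.5, 1.0, 4.0])
        for lam in (-1.0, 0.0, 0.5, 1.0, 2.0):
            z = mixed.boxcox_transform(y, lam)
            np.testing.assert_allclose(mixed.inv_boxcox(z, lam), y, rtol=1e-10)


class TestFitConditionModel:
    def test_forced_zero_variances_match_normal_equations_oracle(self):
        # random variances forced to zero = the OLS path; compare against
        # an independent closed-form least-squares computation
        frame, _ = simulate_features(
            FeatureSimConfig(seed=4, sigma_day=0.0, sigma_coverslip=0.0)
        )
        fit = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax", random=()))
        X = np.column_stack(
            [
                np.ones(len(frame)),
                (frame["line"] == "HT29").to_numpy(float),
                (frame["treatment"] == "DFMO").to_numpy(float),
                (
                    (frame["line"] == "HT29") & (frame["treatment"] == "DFMO")
                ).to_numpy(float),
            ]
        )
        y = frame["soce_dmax"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 4)
        cov_beta = s2 * np.linalg.inv(X.T @ X)
        L = np.array([[1, 0, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]], float)
        np.testing.assert_allclose(fit.means.to_numpy(), L @ beta, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov_means)),
            np.sqrt(np.diag(L @ cov_beta @ L.T)),
            atol=1e-6,
        )

    def test_mixed_fit_on_zero_variance_data_agrees_with_ols_means(self):
        frame, _ = simulate_features(
            FeatureSimConfig(seed=4, sigma_day=0.0, sigma_coverslip=0.0)
        )
        fit_mixed = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax"))
        fit_ols = mixed.fit_condition_model(
            frame, mixed.ModelSpec("soce_dmax", random=())
        )
        np.testing.assert_allclose(fit_mixed.means, fit_ols.means, atol=1e-6)
        # variance components collapse to (near) zero at the boundary
        assert fit_mixed.vc["day"] < 1e-4 and fit_mixed.vc["coverslip"] < 1e-4

    def test_noiseless_data_recovers_configured_means_exactly(self):
        frame, truth = simulate_features(
            FeatureSimConfig(seed=0, sigma_day=0.0, sigma_coverslip=0.0, sigma_cell=0.0)
        )
        fit = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax", random=()))
        np.testing.assert_allclose(
            fit.means.reindex(truth.index), truth, atol=1e-12
        )

    def test_boxcox_backtransform_is_monotone(self):
        frame, _ = simulate_features(FeatureSimConfig(seed=8))
        fit = mixed.fit_condition_model(
            frame, mixed.ModelSpec("soce_dmax", transform=None)
        )
        order_t = fit.means.sort_values().index
        order_o = fit.means_original.sort_values().index
        assert list(order_t) == list(order_o)

    def test_missing_response_errors(self):
        frame, _ = simulate_features(FeatureSimConfig(seed=0, cells_per_coverslip=3))
        with pytest.raises(ValueError, match="response"):
            mixed.fit_condition_model(frame, mixed.ModelSpec("nope"))

    def test_variance_components_recovered_at_scale(self):
        cfg = FeatureSimConfig(
            n_days=12, coverslips_per_condition_day=3, cells_per_coverslip=30,
            sigma_day=0.05, sigma_coverslip=0.04, sigma_cell=0.06, seed=21,
        )
        frame, _ = simulate_features(cfg)
        fit = mixed.fit_condition_model(frame, mixed.ModelSpec(cfg.response))
        assert fit.vc["day"] == pytest.approx(cfg.sigma_day**2, rel=0.8)
        assert fit.vc["coverslip"] == pytest.approx(cfg.sigma_coverslip**2, rel=0.6)
        assert fit.vc["residual"] == pytest.approx(cfg.sigma_cell**2, rel=0.2)


class TestSelectRandomStructure:
    def test_strong_coverslip_variance_selects_nested(self):
        hits = 0
        for rep in range(20):
            frame, _ = simulate_features(
                FeatureSimConfig(seed=300 + rep, sigma_coverslip=0.10, cells_per_coverslip=12)
            )
            spec, _ = mixed.select_random_structure(frame, mixed.ModelSpec("soce_dmax"))
            hits += spec.random == ("day", "coverslip")
        assert hits >= 17

    def test_zero_variances_select_simpler_structure(self):
        hits = 0
        for rep in range(20):
            frame, _ = simulate_features(
                FeatureSimConfig(
                    seed=400 + rep, sigma_day=0.0, sigma_coverslip=0.0,
                    cells_per_coverslip=12,
                )
            )
            spec, _ = mixed.select_random_structure(frame, mixed.ModelSpec("soce_dmax"))
            hits += spec.random == ("day",)
        assert hits > 10

    def test_single_candidate_returned_unchanged(self):
        frame, _ = simulate_features(FeatureSimConfig(seed=0, cells_per_coverslip=3))
        spec, _ = mixed.select_random_structure(
            frame, mixed.ModelSpec("soce_dmax"), candidates=(("day",),)
        )
        assert spec.random == ("day",)

    def test_no_candidates_errors(self):
        frame, _ = simulate_features(FeatureSimConfig(seed=0, cells_per_coverslip=3))
        with pytest.raises(ValueError):
            mixed.select_random_structure(frame, mixed.ModelSpec("soce_dmax"), candidates=())


class TestDiagnostics:
    @staticmethod
    def _ols_fit(seed, n_per=50, dist="normal"):
        rng = np.random.default_rng(seed)
        rows = []
        for cond in CONDITIONS:
            line, treatment = cond.split(":")
            eps = (
                rng.standard_t(2, n_per) if dist == "t2" else rng.standard_normal(n_per)
            )
            for i, e in enumerate(eps):
                rows.append(
                    {
                        "cell_id": f"{cond}{i}",
                        "day": "d1" if i % 2 else "d2",
                        "coverslip": f"{cond}_cv{i % 4}",
                        "line": line,
                        "treatment": treatment,
                        "soce_dmax": 0.5 + 0.05 * e,
                    }
                )
        frame = pd.DataFrame(rows)
        return mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax", random=()))

    def test_shapiro_p_uniform_under_gaussian_errors(self):
        pvals = [
            mixed.check_assumptions(self._ols_fit(seed)).shapiro_p
            for seed in range(200)
        ]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_heavy_tails_detected(self):
        reject = sum(
            mixed.check_assumptions(self._ols_fit(seed, n_per=125, dist="t2")).shapiro_p < 0.05
            for seed in range(60)
        )
        assert reject >= 48  # >= 80%

    def test_constant_residuals_raise(self):
        frame, _ = simulate_features(
            FeatureSimConfig(seed=0, sigma_day=0.0, sigma_coverslip=0.0, sigma_cell=0.0)
        )
        fit = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax", random=()))
        with pytest.raises(ValueError, match="degenerate"):
            mixed.check_assumptions(fit)

    def test_outlier_flagging(self):
        fit = self._ols_fit(0)
        frame = fit.frame.copy()
        frame.loc[frame.index[0], "soce_dmax"] = 5.0  # gross outlier
        fit2 = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax", random=()))
        diag = mixed.check_assumptions(fit2)
        assert 0 in diag.outliers


class TestParametricBootstrap:
    @pytest.fixture(scope="class")
    def small_fit(self):
        frame, _ = simulate_features(
            FeatureSimConfig(seed=2, cells_per_coverslip=10)
        )
        return mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax"))

    def test_same_seed_identical(self, small_fit):
        a = mixed.parametric_bootstrap(small_fit, B=15, seed=3)
        b = mixed.parametric_bootstrap(small_fit, B=15, seed=3)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_b_zero_rejected(self, small_fit):
        with pytest.raises(ValueError):
            mixed.parametric_bootstrap(small_fit, B=0)

    def test_bootstrap_agrees_with_wald(self, small_fit):
        boot = mixed.parametric_bootstrap(small_fit, B=200, seed=5)
        # bootstrap mean within 2 Monte-Carlo SE of the point estimate
        mc_se = boot.samples.std() / np.sqrt(boot.B)
        assert (np.abs(boot.mean - small_fit.means) <= 2.5 * mc_se + 1e-4).all()
        # CI midpoints agree within 10% of the Wald half-width
        wald = small_fit.mean_ci()
        for cond in CONDITIONS:
            mid_boot = 0.5 * (boot.ci_low[cond] + boot.ci_high[cond])
            half = 0.5 * (wald.loc[cond, "ci_high"] - wald.loc[cond, "ci_low"])
            assert abs(mid_boot - wald.loc[cond, "mean"]) <= 0.10 * half + 1e-4


class TestBoxcoxGroupCompare:
    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(0)
        sig = 0
        n_sims = 300
        for _ in range(n_sims):
            y = np.exp(rng.normal(0, 0.5, size=9))
            groups = np.array(["A"] * 6 + ["B"] * 3)
            res = mixed.boxcox_group_compare(y, groups)
            sig += res.p < 0.05
        assert 1 - sig / n_sims >= 0.92

    def test_lognormal_shift_6v3_detected_with_reasonable_power(self):
        rng = np.random.default_rng(1)
        lams, detected = [], 0
        n_sims = 150
        for _ in range(n_sims):
            base = np.exp(rng.normal(0, 0.4, size=9))
            y = np.concatenate([base[:6], base[6:] * 2.0])  # 2-fold shift in B
            res = mixed.boxcox_group_compare(y, np.array(["A"] * 6 + ["B"] * 3))
            lams.append(res.lam)
            detected += res.p < 0.05
        # with n=9 the profile likelihood is flat, but its centre is near log
        assert abs(np.median(lams)) <= 0.9
        assert detected / n_sims > 0.25

    def test_zero_variance_groups_with_distinct_means_separate(self):
        y = np.array([1.0, 1.0, 1.0, 2.0, 2.0])
        res = mixed.boxcox_group_compare(y, np.array(["A"] * 3 + ["B"] * 2))
        assert res.separated and res.p == 0.0

    def test_identical_zero_variance_groups_not_separated(self):
        y = np.ones(6)
        res = mixed.boxcox_group_compare(y, np.array(["A"] * 3 + ["B"] * 3))
        assert not res.separated and res.p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mixed.boxcox_group_compare(
                np.array([1.0, 2.0, 3.0]), np.array(["A", "A", "B"])
            )


def test_bootstrap_ci_shrinks_like_root_n():
    """Percentile CI half-widths scale ~1/sqrt(n) across cell counts."""
    halves = {}
    for n_cells, label in ((4, 128), (16, 512), (64, 2048)):
        frame, _ = simulate_features(
            FeatureSimConfig(seed=77, cells_per_coverslip=n_cells,
                             sigma_day=0.0, sigma_coverslip=0.0)
        )
        fit = mixed.fit_condition_model(frame, mixed.ModelSpec("soce_dmax"))
        boot = mixed.parametric_bootstrap(fit, B=120, seed=7)
        halves[label] = float(
            (boot.ci_high - boot.ci_low).mean() / 2
        )
    r1 = halves[128] / halves[512]
    r2 = halves[512] / halves[2048]
    # quadrupling n should halve the CI width, within MC tolerance
    assert r1 == pytest.approx(2.0, rel=0.35)
    assert r2 == pytest.approx(2.0, rel=0.35)
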