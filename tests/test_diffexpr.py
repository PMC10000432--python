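"""Expression preprocessing, gene-wise models, moderation, FDR."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from caremod import diffexpr
from caremod.simulate import ExprSimConfig, simulate_expression_pair


def balanced_sheet(n_days=4):
    rows = []
    for d in range(n_days):
        for line in ("NCM460", "HT29"):
            for treat in ("control", "DFMO"):
                rows.append(
                    {
                        "sample_id": f"{line}_{treat}_d{d + 1}",
                        "line": line,
                        "treatment": treat,
                        "day": f"d{d + 1}",
                    }
                )
    return pd.DataFrame(rows)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 6.0, 8.0]})
        out = diffexpr.quantile_normalize(mat)
        np.testing.assert_allclose(out["s1"], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out["s2"], [2.5, 4.0, 5.5])

    def test_identical_columns_unchanged(self):
        mat = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        pd.testing.assert_frame_equal(diffexpr.quantile_normalize(mat), mat)

    def test_columns_share_sorted_values_and_idempotent(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(60, 6)))
        out = diffexpr.quantile_normalize(mat)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out:
            np.testing.assert_allclose(np.sort(out[col].to_numpy()), ref)
        pd.testing.assert_frame_equal(diffexpr.quantile_normalize(out), out)

    def test_ties_share_mean_reference(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = diffexpr.quantile_normalize(mat)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_missing_values_rejected(self):
        mat = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            diffexpr.quantile_normalize(mat)


class TestIqrFilter:
    @staticmethod
    def _matrix_with_iqrs(iqrs):
        # rows with uniform spread achieving the requested IQRs
        cols = 5
        base = np.linspace(-0.5, 0.5, cols)  # IQR of this pattern is 0.5
        data = {f"g{i}": iqr / 0.5 * base if iqr else np.zeros(cols) for i, iqr in enumerate(iqrs)}
        return pd.DataFrame(data).T.rename(columns=lambda c: f"s{c}")

    def test_median_threshold_is_strict(self):
        mat = self._matrix_with_iqrs([0.0, 1.0, 2.0, 3.0])
        kept, report = diffexpr.iqr_filter(mat)
        assert set(kept.index) == {"g2", "g3"}
        assert report["n_kept"] == 2

    def test_panel_gene_with_zero_iqr_retained(self):
        mat = self._matrix_with_iqrs([0.0, 1.0, 2.0, 3.0])
        kept, report = diffexpr.iqr_filter(mat, panel_genes=["g0"])
        assert "g0" in kept.index
        assert report["n_panel_rescued"] == 1

    def test_all_equal_iqr_keeps_only_panel(self):
        mat = self._matrix_with_iqrs([1.0, 1.0, 1.0, 1.0])
        kept, _ = diffexpr.iqr_filter(mat, panel_genes=["g1"])
        assert list(kept.index) == ["g1"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.iqr_filter(pd.DataFrame())


class TestGeneLinearModels:
    def test_noiseless_planted_effects_recovered_exactly(self):
        cfg = ExprSimConfig(
            n_genes=2000, sigma_noise=0.0, sigma_day=0.0, platform2_sigma=0.0, seed=2
        )
        mat, _, sheet, truth = simulate_expression_pair(cfg)
        fits = diffexpr.fit_gene_linear_models(mat, sheet)
        np.testing.assert_allclose(fits.coef["line"], truth["a"], atol=1e-10)
        np.testing.assert_allclose(fits.coef["treatment_NCM460"], truth["b"], atol=1e-10)
        np.testing.assert_allclose(
            fits.coef["treatment_HT29"], truth["b"] + truth["c"], atol=1e-10
        )
        np.testing.assert_allclose(fits.coef["interaction"], truth["c"], atol=1e-10)

    def test_residual_df_is_nine_for_16_sample_design(self):
        rng = np.random.default_rng(1)
        sheet = balanced_sheet()
        mat = pd.DataFrame(
            rng.normal(size=(30, 16)), columns=sheet["sample_id"]
        )
        fits = diffexpr.fit_gene_linear_models(mat, sheet)
        assert fits.df_resid == 9  # 16 samples - 7 design columns

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        sheet = balanced_sheet()
        mat = pd.DataFrame(rng.normal(size=(50, 16)), columns=sheet["sample_id"])
        fits = diffexpr.fit_gene_linear_models(mat, sheet)
        X, _ = diffexpr._build_design(sheet)
        for g in range(50):
            beta = np.linalg.solve(X.T @ X, X.T @ mat.iloc[g].to_numpy())
            assert fits.coef["line"].iloc[g] == pytest.approx(beta[1], abs=1e-8)
            assert fits.coef["interaction"].iloc[g] == pytest.approx(beta[3], abs=1e-8)
            resid = mat.iloc[g].to_numpy() - X @ beta
            assert fits.s2[g] == pytest.approx(resid @ resid / 9, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        sheet = balanced_sheet()
        sheet["day"] = np.where(sheet["line"] == "HT29", "d1", "d2")  # day == line
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(12, 16)), columns=sheet["sample_id"])
        with pytest.raises(ValueError, match="confounded"):
            diffexpr.fit_gene_linear_models(mat, sheet)


class TestEbayes:
    @staticmethod
    def _fits(seed=0, G=300, het=True):
        rng = np.random.default_rng(seed)
        sheet = balanced_sheet()
        if het:
            s2 = 0.09 * 4.0 / rng.chisquare(4.0, size=G)
        else:
            s2 = np.full(G, 0.09)
        Y = rng.normal(size=(G, 16)) * np.sqrt(s2)[:, None] + 7.0
        mat = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)], columns=sheet["sample_id"])
        return diffexpr.fit_gene_linear_models(mat, sheet)

    def test_identical_variances_trigger_infinite_prior(self):
        fits = self._fits(het=False)
        fits.s2[:] = 0.09  # force exact equality
        with pytest.warns(RuntimeWarning, match="underdispersed"):
            mod = diffexpr.ebayes_moderate(fits)
        assert np.isinf(mod.d0)
        # closed-form limit: s0^2 is the bias-corrected mean of log s^2
        # (E[log s^2] = log sigma^2 + digamma(d/2) - log(d/2))
        from scipy.special import digamma

        d = fits.df_resid
        s0_expected = np.exp(np.log(0.09) - digamma(d / 2) + np.log(d / 2))
        np.testing.assert_allclose(mod.s2_post, s0_expected, rtol=1e-9)
        # normal reference: t = coef / (u * s0)
        expected_t = fits.coef["line"].to_numpy() / (
            np.sqrt(s0_expected) * fits.stdev_unscaled["line"]
        )
        np.testing.assert_allclose(mod.t["line"], expected_t, rtol=1e-9)

    def test_zero_prior_df_recovers_ordinary_t(self):
        fits = self._fits()
        mod = diffexpr.ebayes_moderate(fits, d0=0.0, s0_sq=1.0)
        ordinary = fits.coef["line"].to_numpy() / (
            np.sqrt(fits.s2) * fits.stdev_unscaled["line"]
        )
        np.testing.assert_allclose(mod.t["line"], ordinary, rtol=1e-12)

    def test_prior_estimation_recovers_simulation_hyperparameters(self):
        fits = self._fits(seed=3, G=4000)
        d0, s0 = diffexpr.estimate_variance_prior(fits.s2, fits.df_resid)
        assert d0 == pytest.approx(4.0, rel=0.35)
        assert s0 == pytest.approx(0.09, rel=0.15)

    def test_moderated_p_monotone_in_abs_t(self):
        fits = self._fits(seed=4)
        mod = diffexpr.ebayes_moderate(fits)
        order = np.argsort(np.abs(mod.t["line"].to_numpy()))
        p_sorted = mod.p["line"].to_numpy()[order]
        assert (np.diff(p_sorted) <= 1e-12).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_moderation_matches_limma_oracle(tmp_path):
    """Independent cross-check of the moderated-t machinery against limma."""
    rng = np.random.default_rng(42)
    G = 150
    sheet = balanced_sheet()
    s2 = 0.09 * 4.0 / rng.chisquare(4.0, size=G)
    Y = 7.0 + rng.normal(size=(G, 16)) * np.sqrt(s2)[:, None]
    mat = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)], columns=sheet["sample_id"])
    fits = diffexpr.fit_gene_linear_models(mat, sheet)
    mod = diffexpr.ebayes_moderate(fits)

    mat.to_csv(tmp_path / "mat.tsv", sep="\t")
    sheet.to_csv(tmp_path / "sheet.tsv", sep="\t", index=False)
    rcode = textwrap.dedent(
        """
        suppressMessages(library(limma))
        mat <- as.matrix(read.delim("mat.tsv", row.names=1, check.names=FALSE))
        sheet <- read.delim("sheet.tsv")
        design <- model.matrix(~ factor(line, c("NCM460","HT29")) *
                                 factor(treatment, c("control","DFMO")) +
                                 factor(day), sheet)
        fit <- eBayes(lmFit(mat, design))
        cat(fit$df.prior, fit$s2.prior, "\\n")
        write.table(data.frame(t=fit$t[,2]), "out.tsv", sep="\\t", quote=FALSE)
        """
    )
    (tmp_path / "oracle.R").write_text(rcode)
    proc = subprocess.run(
        ["Rscript", "oracle.R"], cwd=tmp_path, capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    d0_r, s0_r = map(float, proc.stdout.split())
    lim = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
    assert mod.d0 == pytest.approx(d0_r, rel=0.05)
    assert mod.s0_sq == pytest.approx(s0_r, rel=0.05)
    np.testing.assert_allclose(mod.t["line"].to_numpy(), lim["t"].to_numpy(), atol=0.02)


class TestBhFdr:
    def test_hand_executed_step_up_example(self):
        q = diffexpr.bh_fdr(np.array([0.005, 0.01, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_passthrough(self):
        np.testing.assert_allclose(diffexpr.bh_fdr(np.array([0.2])), [0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_fdr(np.array([0.5, 1.2]))

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        p = np.asarray(pvals)
        q = diffexpr.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        assert q.min() >= p.min() - 1e-12
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestContrastTables:
    def test_planted_up_gene_flagged_with_positive_sign(self):
        cfg = ExprSimConfig(n_genes=500, seed=6)
        mat, _, sheet, truth = simulate_expression_pair(cfg)
        from caremod.panel import load_panel

        tables, _, _ = diffexpr.run_de(mat, sheet, panel=load_panel())
        up = truth.index[(truth["a"] > 0) & truth["is_panel"]]
        line = tables["line"]
        flagged = line.loc[line.index.intersection(up)]
        assert flagged["significant"].mean() > 0.9
        assert (flagged.loc[flagged["significant"], "logFC"] > 0).all()

    def test_zero_q_threshold_flags_nothing(self):
        cfg = ExprSimConfig(n_genes=200, seed=7, use_panel=False)
        mat, _, sheet, _ = simulate_expression_pair(cfg)
        fits = diffexpr.fit_gene_linear_models(mat, sheet)
        mod = diffexpr.ebayes_moderate(fits)
        tables = diffexpr.make_contrast_tables(mod, fdr=0.0)
        assert not tables["line"]["significant"].any()
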