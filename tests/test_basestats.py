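"""Per-base linear model, variance shrinkage, and the moderated t track."""

import subprocess
import textwrap

import numpy as np
import pytest

from derseg.basestats import (
    TransformSpec,
    estimate_shrinkage_prior,
    fit_base_models,
    moderate_statistics,
    posterior_variance,
    read_stat_track,
    transform,
    write_stat_track,
)
from derseg.coverage import DesignMatrix

from conftest import make_cov


class TestTransform:
    @pytest.mark.parametrize(
        "y,offset,expected",
        [(0, 0.5, -1.0), (3.5, 0.5, 2.0), (0, 1.0, 0.0)],
    )
    def test_log2_offset_values(self, y, offset, expected):
        cov = make_cov(np.array([[y]]))
        out = transform(cov, TransformSpec(offset=offset))
        assert out[0, 0] == pytest.approx(expected)

    def test_offset_must_be_positive(self):
        with pytest.raises(ValueError):
            TransformSpec(offset=0.0)


class TestFitBaseModels:
    def test_two_group_hand_example(self, two_group_design):
        # one base, transformed values [1,2,3,4] for groups aabb
        fit = fit_base_models(np.array([[1.0, 2.0, 3.0, 4.0]]),
                              two_group_design, library_norm="none")
        assert fit.beta_hat[0, 0] == pytest.approx(2.0)
        assert fit.resid_var[0] == pytest.approx(0.5)
        assert fit.df_resid == 2
        assert fit.contrast_scale == pytest.approx(1.0)  # 1/2 + 1/2

    def test_constant_row_gives_zero_effect_and_variance(self, two_group_design):
        fit = fit_base_models(np.full((1, 4), 3.0), two_group_design, "none")
        assert fit.beta_hat[0, 0] == pytest.approx(0.0)
        assert fit.resid_var[0] == pytest.approx(0.0, abs=1e-12)

    def test_collinear_confounder_named_in_error(self):
        design = DesignMatrix(
            groups=["a", "a", "b", "b"],
            confounders=np.ones((4, 1)),
            confounder_names=["always_one"],
        )
        with pytest.raises(ValueError, match="always_one"):
            fit_base_models(np.zeros((1, 4)), design, "none")

    def test_matches_direct_normal_equations(self, rng):
        # random small problems against an independent per-row solve
        for _ in range(10):
            n, L = 8, 20
            groups = ["a"] * 4 + ["b"] * 4
            W = rng.normal(size=(n, 1))
            design = DesignMatrix(groups=groups, confounders=W)
            Y = rng.normal(size=(L, n))
            fit = fit_base_models(Y, design, "none")
            X = np.column_stack(
                [np.ones(n), [0] * 4 + [1] * 4, W[:, 0]]
            )
            for j in range(L):
                beta = np.linalg.solve(X.T @ X, X.T @ Y[j])
                assert fit.alpha_hat[j] == pytest.approx(beta[0], rel=1e-10)
                assert fit.beta_hat[j, 0] == pytest.approx(beta[1], rel=1e-10)
                assert fit.gamma_hat[j, 0] == pytest.approx(beta[2], rel=1e-10)


class TestModeration:
    def test_posterior_variance_hand_example(self):
        assert posterior_variance(np.array([0.5]), 2, 4, 1.0)[0] == pytest.approx(5 / 6)
        # and the resulting statistic
        assert 2.0 / np.sqrt(5 / 6) == pytest.approx(2.1909, abs=1e-4)

    def test_no_shrinkage_limit_equals_ordinary_t(self, rng):
        n = 8
        groups = ["a"] * 4 + ["b"] * 4
        design = DesignMatrix(groups=groups)
        counts = rng.integers(20, 60, size=(100, n))
        cov = make_cov(counts)
        Y = transform(cov)
        fit = fit_base_models(Y, design, "none")
        stats = moderate_statistics(fit, cov, cutoff_c=1.0, d0=0.0, s0_sq=1.0)
        expected = fit.beta_hat[:, 0] / np.sqrt(
            fit.resid_var * fit.contrast_scale
        )
        np.testing.assert_allclose(stats.stats, expected, rtol=1e-10)

    def test_posterior_variance_between_sample_and_prior(self, rng):
        s2 = rng.gamma(2.0, 0.5, size=500)
        post = posterior_variance(s2, df=4, d0=3.0, s0_sq=0.8)
        lo = np.minimum(s2, 0.8)
        hi = np.maximum(s2, 0.8)
        assert np.all(post >= lo - 1e-12)
        assert np.all(post <= hi + 1e-12)

    def test_statistic_monotone_in_effect_size(self):
        v = posterior_variance(np.array([0.5]), 2, 4, 1.0)[0]
        betas = np.linspace(-3, 3, 13)
        ts = betas / np.sqrt(v)
        assert np.all(np.diff(ts) > 0)

    def test_identical_variances_shrink_to_themselves(self, two_group_design):
        # all residual variances equal => moment matching returns that value
        cov = make_cov(np.full((60, 4), 40))
        rows = np.tile([1.0, 2.0, 3.0, 4.0], (60, 1))
        fit = fit_base_models(rows, two_group_design, "none")
        d0, s0 = estimate_shrinkage_prior(fit.resid_var, fit.df_resid)
        post = posterior_variance(fit.resid_var, fit.df_resid, d0, s0)
        np.testing.assert_allclose(post, fit.resid_var, rtol=1e-8)

    def test_unexpressed_bases_zeroed_and_masked(self, two_group_design, rng):
        counts = np.vstack(
            [np.zeros((5, 4), int), rng.integers(30, 50, size=(30, 4))]
        )
        cov = make_cov(counts)
        fit = fit_base_models(transform(cov), two_group_design, "none")
        stats = moderate_statistics(fit, cov, cutoff_c=5.0)
        assert not stats.expressed_mask[:5].any()
        assert np.all(stats.stats[:5] == 0.0)
        assert stats.expressed_mask[5:].all()

    def test_too_few_expressed_bases_is_an_error(self, two_group_design):
        cov = make_cov(np.zeros((20, 4), int))
        fit = fit_base_models(transform(cov), two_group_design, "none")
        with pytest.raises(ValueError, match="average coverage"):
            moderate_statistics(fit, cov, cutoff_c=5.0)

    def test_track_round_trip(self, tmp_path, two_group_design, rng):
        counts = rng.integers(10, 50, size=(25, 4))
        cov = make_cov(counts)
        fit = fit_base_models(transform(cov), two_group_design, "none")
        stats = moderate_statistics(fit, cov, cutoff_c=1.0)
        path = tmp_path / "track.tsv"
        write_stat_track(stats, cov, path)
        back = read_stat_track(path)
        np.testing.assert_allclose(back["stat"].to_numpy(), stats.stats, rtol=0, atol=0)
        np.testing.assert_array_equal(
            back["expressed"].to_numpy().astype(bool), stats.expressed_mask
        )


class TestShrinkagePriorOracle:
    def test_prior_recovery_from_simulated_variances(self, rng):
        # variances drawn from the assumed hierarchy: sigma2 ~ s0^2*d0/chi2_d0,
        # s2 ~ sigma2 * chi2_d / d; moment matching should recover (d0, s0^2)
        d0_true, s0_true, df = 8.0, 2.0, 6
        m = 20000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, m)
        s2 = sigma2 * rng.chisquare(df, m) / df
        d0, s0 = estimate_shrinkage_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.05)

    def test_agrees_with_limma_fitfdist(self, tmp_path, rng):
        # independent oracle: limma's moment-matching on the same variances
        df = 6
        sigma2 = 2.0 * 8.0 / rng.chisquare(8.0, 500)
        s2 = sigma2 * rng.chisquare(df, 500) / df
        d0, s0 = estimate_shrinkage_prior(s2, df)
        datafile = tmp_path / "s2.txt"
        np.savetxt(datafile, s2)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            s2 <- scan("{datafile}", quiet=TRUE)
            fit <- fitFDist(s2, df1={df})
            cat(fit$df2, fit$scale, sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        df2_r, scale_r = map(float, out.stdout.split())
        assert d0 == pytest.approx(df2_r, rel=0.05)
        assert s0 == pytest.approx(scale_r, rel=0.05)
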