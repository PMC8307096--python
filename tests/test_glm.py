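"""Hierarchical group GLM: data-scaled priors, sampler correctness,
sum-to-zero identification and contrast posteriors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gshcohort import (
    DegenerateInputError,
    GlmPosterior,
    PosteriorSamples,
    build_priors,
    fit_group_covariate_model,
    fit_group_model,
    group_difference,
    posterior_proportion,
)

FAST = dict(n_kept=1500, thin=1, burn_in=300)


class TestBuildPriors:
    def test_unit_sd_formulas(self, rng):
        y = rng.standard_normal(2000)
        y = (y - y.mean()) / y.std(ddof=1)  # exact mean 0, SD 1
        spec = build_priors(y)
        assert spec.beta0_mean == pytest.approx(0.0, abs=1e-12)
        assert spec.beta0_sd == pytest.approx(5.0)
        assert spec.sigma_beta_shape == pytest.approx(0.5)
        assert spec.sigma_beta_rate == pytest.approx(2.0)
        assert spec.sigma_i_low == pytest.approx(1e-3)
        assert spec.sigma_i_high == pytest.approx(1e3)

    def test_linear_scaling_with_sd(self, rng):
        y = rng.standard_normal(500)
        y = 2.0 * (y - y.mean()) / y.std(ddof=1)
        spec = build_priors(y)
        assert spec.beta0_sd == pytest.approx(10.0)
        assert spec.sigma_beta_shape == pytest.approx(1.0)
        assert spec.sigma_beta_rate == pytest.approx(4.0)

    def test_covariate_prior_sd(self, rng):
        y = 0.3 * rng.standard_normal(300)
        x = 9.0 * rng.standard_normal(300)
        spec = build_priors(y, covariate=x)
        sd_y, sd_x = y.std(ddof=1), x.std(ddof=1)
        assert spec.beta_cov_sd == pytest.approx(2.0 * sd_y / sd_x)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            build_priors(np.ones(10))
        with pytest.raises(DegenerateInputError):
            build_priors(np.arange(10.0), covariate=np.ones(10))


def _two_groups(rng, mu_a, mu_b, n=30, sd=1.0):
    y = np.concatenate([rng.normal(mu_a, sd, n), rng.normal(mu_b, sd, n)])
    g = np.array(["CHR"] * n + ["HC"] * n)
    return y, g


class TestGroupModel:
    def test_parameter_recovery(self, rng):
        y, g = _two_groups(rng, 0.0, 5.0)
        post = fit_group_model(y, g, build_priors(y), seed=1, **FAST)
        assert post.difference.mode == pytest.approx(5.0, abs=0.5)
        assert post.difference.pp > 0.99

    def test_sum_to_zero_exact_every_draw(self, rng):
        y, g = _two_groups(rng, 1.0, 2.0, n=15)
        post = fit_group_model(y, g, build_priors(y), seed=2, **FAST)
        assert np.all(post.deflection("CHR") == -post.deflection("HC"))

    def test_positive_scale_draws(self, rng):
        y, g = _two_groups(rng, 0.0, 1.0, n=10)
        post = fit_group_model(y, g, build_priors(y), seed=3, **FAST)
        assert np.all(post.samples.column("sigma_i") > 0)
        assert np.all(post.samples.column("sigma_beta") > 0)

    def test_label_swap_negates_difference(self, rng):
        y, g = _two_groups(rng, 0.0, 2.0)
        swapped = np.where(g == "CHR", "HC", "CHR")
        a = fit_group_model(y, g, build_priors(y), seed=4, **FAST)
        b = fit_group_model(y, swapped, build_priors(y), seed=4, **FAST)
        assert a.difference.mode == pytest.approx(-b.difference.mode, abs=0.3)

    def test_null_calibration_single_dataset(self, rng):
        y, g = _two_groups(rng, 10.0, 10.0)
        post = fit_group_model(y, g, build_priors(y), seed=5, **FAST)
        # same population: difference posterior should cover zero
        assert post.difference.hdi_low <= 0.0 <= post.difference.hdi_high

    def test_pp_symmetry_between_difference_and_deflection(self, rng):
        y, g = _two_groups(rng, 0.0, 1.0, n=20)
        post = fit_group_model(y, g, build_priors(y), seed=6, **FAST)
        diff = post.deflection("HC") - post.deflection("CHR")
        assert posterior_proportion(diff) == posterior_proportion(2 * post.deflection("CHR"))

    def test_shrinkage_pulls_difference_toward_zero(self, rng):
        y, g = _two_groups(rng, 0.0, 0.8, n=8)
        spec = build_priors(y)
        # severely informative hyperprior concentrating sigma_beta near zero
        tight = dataclasses.replace(spec, sigma_beta_shape=2.0, sigma_beta_rate=200.0)
        post = fit_group_model(y, g, tight, seed=7, **FAST)
        raw_diff = y[g == "HC"].mean() - y[g == "CHR"].mean()
        assert abs(post.difference.mean) < abs(raw_diff)

    def test_empty_group_rejected(self, rng):
        y = rng.normal(size=10)
        with pytest.raises(DegenerateInputError):
            fit_group_model(y, np.array(["CHR"] * 10), build_priors(y), **FAST)

    def test_single_member_group_warns_not_fails(self, rng):
        y = np.concatenate([rng.normal(0, 1, 1), rng.normal(0, 1, 12)])
        g = np.array(["CHR"] + ["HC"] * 12)
        with pytest.warns(UserWarning, match="single member"):
            post = fit_group_model(y, g, build_priors(y), seed=8, **FAST)
        assert post.difference.hdi_high > post.difference.hdi_low

    def test_deterministic_given_seed(self, rng):
        y, g = _two_groups(rng, 0.0, 1.0, n=10)
        spec = build_priors(y)
        a = fit_group_model(y, g, spec, seed=9, **FAST)
        b = fit_group_model(y, g, spec, seed=9, **FAST)
        assert a.samples.draws.equals(b.samples.draws)


class TestCovariateModel:
    def test_slope_recovery_inflated_n(self, rng):
        n, nc = 430, 130
        sofas = rng.normal(75, 9, n)
        g = np.array(["CHR"] * nc + ["HC"] * (n - nc))
        ind = (g == "CHR").astype(float)
        y = 1.6 + 0.15 * ind + 0.01 * (sofas - sofas.mean()) + rng.normal(0, 0.25, n)
        spec = build_priors(y, covariate=sofas)
        post = fit_group_covariate_model(y, g, sofas, spec, seed=10, **FAST)
        assert post.summaries["beta_cov"].mode == pytest.approx(0.01, abs=0.005)

    def test_unrelated_covariate_stays_null(self, rng):
        y, g = _two_groups(rng, 1.5, 1.5, n=25, sd=0.3)
        x = rng.normal(70, 10, y.size)
        spec = build_priors(y, covariate=x)
        post = fit_group_covariate_model(y, g, x, spec, seed=11, **FAST)
        assert post.summaries["beta_cov"].hdi_low <= 0.0 <= post.summaries["beta_cov"].hdi_high

    def test_inert_covariate_reduces_to_group_model(self, rng):
        y, g = _two_groups(rng, 10.0, 11.0, n=15)
        spec = build_priors(y)
        spec_cov = dataclasses.replace(spec, beta_cov_sd=1.0)
        a = fit_group_model(y, g, spec, seed=12, **FAST)
        b = fit_group_covariate_model(y, g, np.zeros_like(y), spec_cov, seed=12, **FAST)
        shared = [c for c in a.samples.draws.columns]
        assert all(a.samples.draws[c].equals(b.samples.draws[c]) for c in shared)

    def test_requires_cov_prior_sd(self, rng):
        y, g = _two_groups(rng, 0.0, 1.0, n=10)
        with pytest.raises(ValueError):
            fit_group_covariate_model(y, g, rng.normal(size=y.size), build_priors(y), **FAST)


class TestGroupDifference:
    def _synthetic_post(self, diff_draws, sigma_draws):
        n = len(diff_draws)
        d = np.asarray(diff_draws, dtype=float) / 2.0
        df = pd.DataFrame({
            "beta0": np.zeros(n), "beta_CHR": -d, "beta_HC": d,
            "sigma_beta": np.ones(n), "sigma_i": np.asarray(sigma_draws, dtype=float),
        })
        samples = PosteriorSamples(draws=df, thin=1, burn_in=0, seed=0)
        return GlmPosterior(samples=samples, summaries={}, difference=None,
                            effect_size=None, labels=("CHR", "HC"))

    def test_zero_deflections_give_pp_half(self):
        post = self._synthetic_post(np.zeros(100), np.ones(100))
        diff, es = group_difference(post, "HC", "CHR")
        assert diff.mean == 0.0 and diff.pp == 0.5

    def test_ratio_identity_with_unit_sigma(self):
        post = self._synthetic_post(np.full(100, 0.5), np.ones(100))
        _, es = group_difference(post, "HC", "CHR")
        assert es.mean == pytest.approx(0.5)
        assert es.mode == pytest.approx(0.5)

    def test_unknown_label_rejected(self):
        post = self._synthetic_post(np.zeros(100), np.ones(100))
        with pytest.raises(KeyError):
            group_difference(post, "HC", "XX")

    def test_effect_size_consistency_with_reported_scale(self, rng):
        # difference concentrated near -0.27 with residual SD near 0.264
        diff = rng.normal(-0.27, 0.02, 4000)
        sigma = np.exp(rng.normal(np.log(0.264), 0.03, 4000))
        post = self._synthetic_post(diff, sigma)
        _, es = group_difference(post, "HC", "CHR")
        assert -1.2 < es.mode < -0.9
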