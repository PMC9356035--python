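"""ABC machinery tests: rejection, GLM posterior (conjugate oracle), model
choice, cross-validation, accuracy indices and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from danubesim import inference as inf
from danubesim.inference import (
    PriorSpec,
    abc_glm_posterior,
    bias_rmse_factor2,
    build_reference_table,
    calibration_diagnostics,
    cross_validate_recovery,
    hdi,
    hdi_level_of,
    marginal_density_pvalue,
    model_choice,
    posterior_quantile,
    retain,
)


def gaussian_toy_table(n, seed, shift=0.0, scenario="toy", sigma=1.0):
    """Reference table of the linear-Gaussian toy s = theta + shift + noise."""
    priors = PriorSpec(bounds={"theta": (-10.0, 10.0)})

    def sim(params, s):
        r = np.random.default_rng(s)
        return [params["theta"] + shift + r.normal(0, sigma)]

    return build_reference_table(sim, priors, n, seed, scenario_id=scenario), priors


class TestPriorsAndTable:
    def test_prior_draws_inside_bounds(self):
        priors = PriorSpec(bounds={"a": (0.0, 1.0), "b": (5.0, 6.0)})
        draws = priors.sample(np.random.default_rng(0), 10_000)
        assert draws["a"].between(0, 1).all()
        assert draws["b"].between(5, 6).all()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(bounds={"a": (1.0, 1.0)})

    def test_empty_table(self):
        table, _ = gaussian_toy_table(0, seed=0)
        assert len(table) == 0

    def test_fixed_seed_reproducible(self):
        t1, _ = gaussian_toy_table(50, seed=4)
        t2, _ = gaussian_toy_table(50, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_failures_are_resampled_and_counted(self):
        priors = PriorSpec(bounds={"theta": (0.0, 1.0)})
        calls = {"n": 0}

        def flaky(params, seed):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise inf.SimulationFailure("boom")
            return [params["theta"]]

        table = build_reference_table(flaky, priors, 30, seed=1)
        assert len(table) == 30
        assert table.attrs["n_failures"] > 0


class TestRetention:
    def test_delta_one_retains_everything(self):
        table, _ = gaussian_toy_table(500, seed=1)
        kept, _ = retain([0.0], table, 1.0)
        assert len(kept) == 500

    def test_retained_count_is_ceil_delta_n(self):
        table, _ = gaussian_toy_table(1000, seed=1)
        kept, _ = retain([0.0], table, 0.01)
        assert len(kept) == 10
        kept, _ = retain([0.0], table, 0.0151)
        assert len(kept) == 16

    def test_observed_equal_to_a_row_has_zero_distance(self):
        table, _ = gaussian_toy_table(200, seed=2)
        obs = [float(table["stat_s0"].iloc[17])]
        kept, dist = retain(obs, table, 0.05)
        assert kept["abc_distance"].min() == 0.0
        assert 17 in kept.index

    def test_tiny_retention_errors(self):
        table, _ = gaussian_toy_table(10, seed=3)
        with pytest.raises(ValueError):
            retain([0.0], table, 0.0)


class TestGLMPosterior:
    def test_conjugate_linear_gaussian_oracle(self):
        """With a flat prior and s = theta + e, e ~ N(0,1), the posterior
        given s_obs is N(s_obs, 1); the GLM fitted on the full table must
        reproduce it within Monte-Carlo error."""
        table, priors = gaussian_toy_table(20_000, seed=10)
        obs = [0.5]
        kept, _ = retain(obs, table, 1.0)
        post = abc_glm_posterior(kept, priors, obs)
        pp = post.params["theta"]
        var = np.trapezoid((pp.grid - pp.mean) ** 2 * pp.density, pp.grid)
        assert post.method == "glm"
        assert pp.mean == pytest.approx(0.5, abs=0.1)
        assert np.sqrt(var) == pytest.approx(1.0, rel=0.1)
        # HDI of a Gaussian ~ equal-tailed interval
        assert pp.hdi90[0] == pytest.approx(0.5 - 1.645, abs=0.2)
        assert pp.hdi90[1] == pytest.approx(0.5 + 1.645, abs=0.2)

    def test_posterior_mass_respects_prior_truncation(self):
        table, priors = gaussian_toy_table(5_000, seed=11)
        obs = [9.9]  # near the upper prior bound
        kept, _ = retain(obs, table, 1.0)
        post = abc_glm_posterior(kept, priors, obs)
        pp = post.params["theta"]
        assert pp.grid[0] >= -10.0 and pp.grid[-1] <= 10.0
        assert pp.hdi90[1] <= 10.0

    def test_uninformative_statistic_returns_the_prior(self):
        """A statistic carrying no signal about the parameter leaves its
        marginal flat (compared with uniform by sup-CDF distance)."""
        priors = PriorSpec(bounds={"theta": (0.0, 1.0)})

        def sim(params, s):
            return [np.random.default_rng(s).normal()]

        table = build_reference_table(sim, priors, 4000, seed=12)
        kept, _ = retain([0.0], table, 0.5)
        post = abc_glm_posterior(kept, priors, [0.0])
        pp = post.params["theta"]
        dx = pp.grid[1] - pp.grid[0]
        cdf = np.cumsum(pp.density) * dx
        uniform_cdf = (pp.grid - pp.grid[0]) / (pp.grid[-1] - pp.grid[0])
        assert np.max(np.abs(cdf - uniform_cdf)) < 0.08

    def test_two_parameter_joint_grid(self):
        priors = PriorSpec(bounds={"a": (0.0, 1.0), "b": (0.0, 1.0)})

        def sim(params, s):
            r = np.random.default_rng(s)
            return [
                params["a"] + r.normal(0, 0.05),
                params["b"] + r.normal(0, 0.05),
            ]

        table = build_reference_table(sim, priors, 3000, seed=13)
        obs = [0.3, 0.7]
        kept, _ = retain(obs, table, 1.0)
        post = abc_glm_posterior(kept, priors, obs)
        assert post.params["a"].mode == pytest.approx(0.3, abs=0.05)
        assert post.params["b"].mode == pytest.approx(0.7, abs=0.05)

    def test_min_retained_enforced(self):
        table, priors = gaussian_toy_table(60, seed=14)
        kept, _ = retain([0.0], table, 0.5)
        with pytest.raises(ValueError):
            abc_glm_posterior(kept.iloc[:20], priors, [0.0])


class TestMarginalDensityPValue:
    def test_central_observation_fits_well(self):
        """For a Gaussian retained cloud, the centroid has close to the
        highest marginal density."""
        rng = np.random.default_rng(20)
        table = pd.DataFrame(
            {
                "scenario": "toy",
                "seed": 0,
                "param_theta": rng.uniform(size=1000),
                "stat_s0": rng.normal(size=1000),
            }
        )
        assert marginal_density_pvalue(table, [0.0]) > 0.8

    def test_far_observation_fits_poorly(self):
        table, _ = gaussian_toy_table(1000, seed=21)
        kept, _ = retain([0.0], table, 0.5)
        assert marginal_density_pvalue(kept, [40.0]) < 0.05

    def test_density_rank_oracle_on_gaussian_cloud(self):
        """Observed at the 10th percentile of the density ranking -> P ~ 0.1."""
        rng = np.random.default_rng(22)
        s = rng.normal(size=800)
        table = pd.DataFrame(
            {
                "scenario": "toy",
                "seed": 0,
                "param_theta": rng.uniform(size=800),
                "stat_s0": s,
            }
        )
        obs = [float(np.quantile(np.abs(s), 0.9))]
        p = marginal_density_pvalue(table, obs)
        assert p == pytest.approx(0.10, abs=0.04)


class TestModelChoice:
    def test_identical_generative_processes_are_equiprobable(self):
        tA, _ = gaussian_toy_table(4000, seed=30, scenario="A")
        tB, _ = gaussian_toy_table(4000, seed=31, scenario="B")
        res = model_choice([0.2], {"A": tA, "B": tB}, delta=0.05, fit_pvalues=False)
        assert res.posterior_prob["A"] == pytest.approx(0.5, abs=0.15)
        assert sum(res.posterior_prob.values()) == pytest.approx(1.0)
        for eps, fr in res.pritchard.items():
            assert sum(fr.values()) == pytest.approx(1.0)
            assert fr["A"] == pytest.approx(0.5, abs=0.2)

    def test_separated_models_identified(self):
        tA, _ = gaussian_toy_table(4000, seed=32, scenario="A")
        tB, _ = gaussian_toy_table(4000, seed=33, shift=100.0, scenario="B")
        res = model_choice([0.2], {"A": tA, "B": tB}, delta=0.05, fit_pvalues=False)
        assert res.posterior_prob["A"] > 0.99
        assert res.bayes_factor["A"] > 100
        assert res.pritchard[0.01]["A"] == pytest.approx(1.0)

    def test_single_table_rejected(self):
        tA, _ = gaussian_toy_table(100, seed=34)
        with pytest.raises(ValueError, match="at least 2"):
            model_choice([0.0], {"A": tA})

    def test_unequal_sizes_rejected(self):
        tA, _ = gaussian_toy_table(100, seed=35, scenario="A")
        tB, _ = gaussian_toy_table(99, seed=36, scenario="B")
        with pytest.raises(ValueError, match="equal sizes"):
            model_choice([0.0], {"A": tA, "B": tB})

    def test_pritchard_retained_count(self):
        tA, _ = gaussian_toy_table(2000, seed=37, scenario="A")
        tB, _ = gaussian_toy_table(2000, seed=38, scenario="B")
        res = model_choice([0.0], {"A": tA, "B": tB}, delta=0.05, fit_pvalues=False)
        # 1% of the pooled 4000 simulations = 40; fractions over that set
        assert set(res.pritchard) == {0.0025, 0.01, 0.025}


class TestCrossValidation:
    def test_chance_level_for_identical_models(self):
        tA, _ = gaussian_toy_table(1500, seed=40, scenario="A")
        tB, _ = gaussian_toy_table(1500, seed=41, scenario="B")
        pr = cross_validate_recovery({"A": tA, "B": tB}, delta=0.05, n_pseudo=40, seed=1)
        for scen in ("A", "B"):
            assert pr[scen] == pytest.approx(0.5, abs=0.2)

    def test_perfect_recovery_for_separated_models(self):
        tA, _ = gaussian_toy_table(1500, seed=42, scenario="A")
        tB, _ = gaussian_toy_table(1500, seed=43, shift=100.0, scenario="B")
        pr = cross_validate_recovery({"A": tA, "B": tB}, delta=0.05, n_pseudo=30, seed=2)
        assert pr["A"] >= 0.97
        assert pr["B"] >= 0.97

    def test_fixed_seed_reproducible(self):
        tA, _ = gaussian_toy_table(800, seed=44, scenario="A")
        tB, _ = gaussian_toy_table(800, seed=45, scenario="B")
        pr1 = cross_validate_recovery({"A": tA, "B": tB}, delta=0.1, n_pseudo=10, seed=3)
        pr2 = cross_validate_recovery({"A": tA, "B": tB}, delta=0.1, n_pseudo=10, seed=3)
        assert pr1 == pr2


class TestAccuracyIndices:
    def test_perfect_estimates(self):
        assert bias_rmse_factor2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 1.0)

    def test_hand_computed_toy(self):
        bias, rmse, f2 = bias_rmse_factor2([1.0, 2.0], [2.0, 1.0])
        assert bias == pytest.approx(0.75)
        assert rmse == pytest.approx((1 / 1.5) * np.sqrt(1.0))
        assert f2 == 1.0

    def test_factor2_boundary_inclusive(self):
        t = np.array([1.0, 4.0, 10.0])
        _, _, f2 = bias_rmse_factor2(t, 2.0 * t)
        assert f2 == 1.0
        _, _, f2 = bias_rmse_factor2(t, 0.5 * t)
        assert f2 == 1.0
        _, _, f2 = bias_rmse_factor2(t, 2.001 * t)
        assert f2 == 0.0

    def test_zero_true_value_rejected(self):
        with pytest.raises(ValueError):
            bias_rmse_factor2([0.0, 1.0], [1.0, 1.0])


class TestHDI:
    def test_gaussian_hdi_matches_equal_tailed(self):
        grid = np.linspace(-6, 6, 2001)
        dens = sp_stats.norm.pdf(grid)
        lo, hi = hdi(grid, dens, 0.9)
        assert lo == pytest.approx(-1.645, abs=0.02)
        assert hi == pytest.approx(1.645, abs=0.02)

    def test_hdi50_nested_in_hdi90(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 1, 1001)
        dens = np.exp(-0.5 * ((grid - 0.3) / 0.1) ** 2) + 0.2
        l50, h50 = hdi(grid, dens, 0.5)
        l90, h90 = hdi(grid, dens, 0.9)
        assert l90 <= l50 <= h50 <= h90

    def test_level_near_one_covers_support(self):
        grid = np.linspace(0, 1, 501)
        dens = np.ones_like(grid)
        lo, hi = hdi(grid, dens, 0.999)
        assert lo <= 0.01 and hi >= 0.99

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            hdi(np.linspace(0, 1, 10), np.ones(10), 1.5)


class TestCalibration:
    @staticmethod
    def _gaussian_posterior(mean, sd=1.0):
        from danubesim.inference import ParamPosterior, PosteriorResult

        grid = np.linspace(mean - 6 * sd, mean + 6 * sd, 1024)
        dens = sp_stats.norm.pdf(grid, mean, sd)
        lo50, hi50 = hdi(grid, dens, 0.5)
        lo90, hi90 = hdi(grid, dens, 0.9)
        pp = ParamPosterior(
            name="theta", grid=grid, density=dens,
            mode=float(grid[np.argmax(dens)]),
            mean=float(np.trapezoid(grid * dens, grid)),
            hdi50=(lo50, hi50), hdi90=(lo90, hi90),
        )
        return PosteriorResult(params={"theta": pp}, retained_index=np.arange(1), method="glm")

    def test_exact_posteriors_pass_uniformity(self):
        """True values drawn from their own posterior: quantiles uniform."""
        rng = np.random.default_rng(50)
        posts, truths = [], []
        for _ in range(300):
            mu = rng.uniform(2, 8)
            posts.append(self._gaussian_posterior(mu))
            truths.append({"theta": rng.normal(mu, 1.0)})
        report = calibration_diagnostics(posts, pd.DataFrame(truths))
        assert report.ks_quantile_p["theta"] > 0.01
        assert report.ks_hdi_p["theta"] > 0.01

    def test_gross_bias_detected(self):
        rng = np.random.default_rng(51)
        posts, truths = [], []
        for _ in range(200):
            mu = rng.uniform(2, 8)
            posts.append(self._gaussian_posterior(mu))
            truths.append({"theta": mu + 3.0})  # always in the upper tail
        report = calibration_diagnostics(posts, pd.DataFrame(truths))
        assert report.ks_quantile_p["theta"] < 1e-3

    def test_quantile_and_hdi_level_helpers(self):
        grid = np.linspace(-6, 6, 2001)
        dens = sp_stats.norm.pdf(grid)
        assert posterior_quantile(grid, dens, 0.0) == pytest.approx(0.5, abs=0.01)
        assert posterior_quantile(grid, dens, 1.645) == pytest.approx(0.95, abs=0.01)
        assert hdi_level_of(grid, dens, 0.0) == pytest.approx(0.0, abs=0.02)
        assert hdi_level_of(grid, dens, 1.96) == pytest.approx(0.95, abs=0.02)
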