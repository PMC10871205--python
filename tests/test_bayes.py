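"""Bayesian group-by-time model, HDI, p_difference, PPC, regression."""

import numpy as np
import pandas as pd
import pytest

from splitbelt import (
    GroupTimeModelSpec,
    bayesian_regression,
    fit_group_time_model,
    hdi,
    likelihood_comparison,
    p_difference,
    posterior_predictive_check,
)

from conftest import make_group_time_data

# reduced draw counts keep replicate studies fast; summaries stay stable
FAST = GroupTimeModelSpec(n_draws=4000, n_tune=1000, thin=4, seed=0)


class TestHdi:
    def test_standard_normal_quantiles(self):
        d = np.random.default_rng(0).normal(size=100_000)
        lo, hi = hdi(d, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_exponential_one_sided(self):
        """For a monotone density the shortest 95% interval is [0, -ln(0.05)]."""
        d = np.random.default_rng(1).exponential(size=100_000)
        lo, hi = hdi(d, 0.95)
        assert lo == pytest.approx(0.0, abs=0.05)
        assert hi == pytest.approx(2.996, abs=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = hdi(np.full(500, 3.3))
        assert lo == hi == pytest.approx(3.3)

    def test_matches_symmetric_equal_tail_interval(self):
        d = np.random.default_rng(2).normal(2.0, 0.5, 200_000)
        lo, hi = hdi(d, 0.95)
        qlo, qhi = np.percentile(d, [2.5, 97.5])
        assert lo == pytest.approx(qlo, abs=0.02)
        assert hi == pytest.approx(qhi, abs=0.02)

    def test_agrees_with_arviz(self):
        import arviz as az
        d = np.random.default_rng(3).gamma(2.0, size=50_000)
        lo, hi = hdi(d, 0.9)
        ref = az.hdi(d, hdi_prob=0.9)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(100), mass=1.5)


class TestPDifference:
    def test_all_positive(self):
        assert p_difference(np.ones(100)) == 100.0

    def test_exact_share(self):
        d = np.concatenate([np.ones(943), -np.ones(57)])
        assert p_difference(d) == pytest.approx(94.3)

    def test_sign_symmetry(self):
        d = np.random.default_rng(4).normal(0.3, 1, 10_000)
        assert p_difference(d) == p_difference(-d)

    def test_zeros_split_evenly(self):
        assert p_difference(np.zeros(10)) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            p_difference(np.array([]))


class TestGroupTimeModel:
    def test_balanced_null_centered_posteriors(self):
        """The same values in every cell: effects 0, p_difference near 50."""
        rng = np.random.default_rng(5)
        cell = rng.normal(0.5, 0.1, 18)
        rows = [{"group": g, "time": t, "value": v}
                for g in ("a", "b") for t in ("T1", "T2") for v in cell]
        fit = fit_group_time_model(pd.DataFrame(rows), FAST)
        for name in ("group", "time", "interaction"):
            s = fit[name]
            assert abs(s.mean) < 0.02
            assert s.p_difference < 65.0
            assert s.hdi_low < 0 < s.hdi_high

    def test_interaction_recovery(self):
        """Known interaction 0.09 recovered within +-0.03 on average."""
        rng = np.random.default_rng(6)
        means = []
        for rep in range(10):
            data = make_group_time_data(rng, effects=(0.5, 0.1, 0.05, 0.09), sd=0.1)
            spec = GroupTimeModelSpec(n_draws=4000, n_tune=1000, thin=4, seed=rep)
            fit = fit_group_time_model(data, spec)
            means.append(fit["interaction"].mean)
        assert np.mean(means) == pytest.approx(0.09, abs=0.03)

    def test_prior_insensitivity(self):
        """10x wider priors shift posterior means by less than MC error."""
        rng = np.random.default_rng(7)
        data = make_group_time_data(rng)
        f1 = fit_group_time_model(data, FAST)
        wide = GroupTimeModelSpec(n_draws=4000, n_tune=1000, thin=4,
                                  prior_scale=100.0, seed=0)
        f2 = fit_group_time_model(data, wide)
        for name in ("group", "time", "interaction"):
            mc_err = f1[name].draws.std() / np.sqrt(f1[name].ess)
            assert abs(f1[name].mean - f2[name].mean) < 4 * mc_err

    def test_determinism(self):
        rng = np.random.default_rng(8)
        data = make_group_time_data(rng)
        f1 = fit_group_time_model(data, FAST)
        f2 = fit_group_time_model(data, FAST)
        np.testing.assert_array_equal(f1["interaction"].draws,
                                      f2["interaction"].draws)

    def test_cell_requirements(self):
        rows = [{"group": "a", "time": "T1", "value": 1.0},
                {"group": "a", "time": "T2", "value": 2.0}]
        with pytest.raises(ValueError):
            fit_group_time_model(pd.DataFrame(rows), FAST)


class TestPosteriorPredictiveCheck:
    def test_self_generated_data_rarely_flagged(self):
        rng = np.random.default_rng(9)
        clean = 0
        for rep in range(10):
            data = make_group_time_data(rng, sd=0.1)
            spec = GroupTimeModelSpec(n_draws=4000, n_tune=1000, thin=4, seed=rep)
            fit = fit_group_time_model(data, spec)
            ppc = posterior_predictive_check(fit, seed=rep)
            clean += int(not ppc["flagged"].any())
        assert clean >= 9

    def test_heavy_tail_contamination_flags_sd(self):
        rng = np.random.default_rng(10)
        data = make_group_time_data(rng, sd=0.05)
        # a gross outlier in one cell inflates the observed SD beyond replication
        idx = data[(data["group"] == "stroke") & (data["time"] == "FeedbackOn")].index
        data.loc[idx[0], "value"] += 3.0
        fit = fit_group_time_model(data, FAST)
        ppc = posterior_predictive_check(fit, seed=0)
        assert ppc[(ppc["stat"] == "sd")]["flagged"].any()

    def test_replicated_means_track_observed(self):
        rng = np.random.default_rng(11)
        data = make_group_time_data(rng)
        fit = fit_group_time_model(data, FAST)
        ppc = posterior_predictive_check(fit, n_rep=1000, seed=1)
        means = ppc[ppc["stat"] == "mean"]
        np.testing.assert_allclose(means["replicated_mean"], means["observed"],
                                   atol=0.05)


class TestBayesianRegression:
    def test_slope_recovery(self):
        rng = np.random.default_rng(12)
        x = rng.normal(25, 6, 17)
        y = 2.0 * x + rng.normal(0, 0.1, 17)
        out = bayesian_regression(y, x, FAST)
        assert out["slope"].mean == pytest.approx(2.0, abs=0.1)
        assert out["slope"].hdi_low < 2.0 < out["slope"].hdi_high

    def test_null_slope_hdi_covers_zero(self):
        rng = np.random.default_rng(13)
        covered = 0
        for rep in range(10):
            x = rng.normal(25, 6, 17)
            y = rng.normal(0.5, 0.1, 17)
            out = bayesian_regression(y, x, FAST)
            covered += int(out["slope"].hdi_low <= 0 <= out["slope"].hdi_high)
        assert covered >= 8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            bayesian_regression(np.arange(10.0), np.full(10, 3.0), FAST)


class TestLikelihoodComparison:
    def test_normal_data_prefers_normal_or_ties(self):
        rng = np.random.default_rng(14)
        wins = 0
        for rep in range(5):
            data = make_group_time_data(rng, sd=0.1)
            spec = GroupTimeModelSpec(n_draws=2000, n_tune=1000, thin=2, seed=rep)
            cmp = likelihood_comparison(data, spec)
            wins += int(cmp.preferred == "normal" or abs(cmp.elpd_diff) < 2.0)
        assert wins >= 4

    def test_heavy_tail_data_prefers_student_t(self):
        rng = np.random.default_rng(15)
        wins = 0
        for rep in range(5):
            data = make_group_time_data(rng, sd=0.05)
            contaminated = data.copy()
            take = rng.choice(len(data), size=6, replace=False)
            contaminated.loc[take, "value"] += rng.choice([-1, 1], 6) * 1.0
            spec = GroupTimeModelSpec(n_draws=2000, n_tune=1000, thin=2, seed=rep)
            cmp = likelihood_comparison(contaminated, spec)
            wins += int(cmp.preferred == "student_t")
        assert wins >= 3

    def test_deterministic_at_fixed_seed(self):
        rng = np.random.default_rng(16)
        data = make_group_time_data(rng)
        spec = GroupTimeModelSpec(n_draws=2000, n_tune=1000, thin=2, seed=3)
        c1 = likelihood_comparison(data, spec)
        c2 = likelihood_comparison(data, spec)
        assert c1.elpd_normal == c2.elpd_normal
        assert c1.elpd_student_t == c2.elpd_student_t
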