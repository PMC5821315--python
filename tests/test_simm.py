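"""Tests for the Bayesian mixing model: moments, likelihood, priors, sampler."""

import math

import numpy as np
import pytest
from scipy import stats

import sealsimm as ss
from sealsimm.simm import split_rhat

SHORT = dict(chains=3, iterations=20_000, burn_in=5_000, thin=5)


def _groups(specs):
    return [
        ss.SourceGroup(name, (name,), 5, c_m, c_sd, n_m, n_sd)
        for name, c_m, c_sd, n_m, n_sd in specs
    ]


WELL_SEPARATED = _groups(
    [
        ("A", -20.0, 0.3, 8.0, 0.3),
        ("B", -14.0, 0.3, 8.5, 0.3),
        ("C", -17.0, 0.3, 16.0, 0.3),
    ]
)
TIGHT_TEF = ss.TEFSpec("truth", "vibrissae", 0.5, 0.1, 3.0, 0.1)


def _consumer(d13C, d15N, cid="c1"):
    return ss.IsotopeRecord(cid, "consumer", cid, "vibrissae", "unknown", d13C, d15N, 3.0)


class TestMixtureMoments:
    def test_single_source(self):
        mean, var = ss.mixture_moments([1.0, 0.0, 0.0], WELL_SEPARATED, TIGHT_TEF)
        assert mean == pytest.approx([-20.0 + 0.5, 8.0 + 3.0])
        assert var == pytest.approx([0.3**2 + 0.1**2, 0.3**2 + 0.1**2])

    def test_identical_groups_mean_independent_of_p(self):
        same = _groups([("A", -17.0, 0.5, 12.0, 1.0)] * 3)
        same = [
            ss.SourceGroup(f"g{i}", (f"g{i}",), 5, -17.0, 0.5, 12.0, 1.0) for i in range(3)
        ]
        m1, _ = ss.mixture_moments([1 / 3] * 3, same, TIGHT_TEF)
        m2, _ = ss.mixture_moments([0.8, 0.1, 0.1], same, TIGHT_TEF)
        assert m1 == pytest.approx(m2)

    def test_three_source_hand_arithmetic(self, three_groups, post_tef_vib):
        """Equal-thirds mixture of the pooled squid / sand lance / demersal
        groups under the ecosystem-average TEF, against hand-computed sums."""
        p = np.full(3, 1 / 3)
        mean, var = ss.mixture_moments(p, three_groups, post_tef_vib)
        mu = np.array([[g.d13C_mean, g.d15N_mean] for g in three_groups])
        s2 = np.array([[g.d13C_sd**2, g.d15N_sd**2] for g in three_groups])
        want_mean = mu.mean(axis=0) + np.array([0.4, 3.4])
        want_var = ((1 / 9) * (s2 + np.array([1.3**2, 0.98**2]))).sum(axis=0)
        assert mean == pytest.approx(want_mean, abs=1e-12)
        assert var == pytest.approx(want_var, abs=1e-12)

    def test_off_simplex_rejected(self, three_groups, post_tef_vib):
        with pytest.raises(ValueError, match="simplex"):
            ss.mixture_moments([0.5, 0.5, 0.5], three_groups, post_tef_vib)


class TestLogLikelihood:
    def test_consumer_at_mixture_mean_peak_density(self):
        p = [0.2, 0.3, 0.5]
        mean, var = ss.mixture_moments(p, WELL_SEPARATED, TIGHT_TEF)
        c = _consumer(*mean)
        ll = ss.log_likelihood(p, None, [c], WELL_SEPARATED, TIGHT_TEF, "process")
        want = sum(-0.5 * math.log(2 * math.pi * v) for v in var)
        assert ll == pytest.approx(want, abs=1e-12)

    def test_doubling_variance_lowers_peak(self):
        p = [0.2, 0.3, 0.5]
        mean, _ = ss.mixture_moments(p, WELL_SEPARATED, TIGHT_TEF)
        c = _consumer(*mean)
        base = ss.log_likelihood(p, [1.0, 1.0], [c], WELL_SEPARATED, TIGHT_TEF)
        doubled = ss.log_likelihood(p, [math.sqrt(2)] * 2, [c], WELL_SEPARATED, TIGHT_TEF)
        assert base - doubled == pytest.approx(2 * math.log(math.sqrt(2)), abs=1e-12)

    def test_matches_direct_density_product(self, three_groups, post_tef_vib, rng):
        p = np.array([0.25, 0.15, 0.6])
        s = np.array([1.3, 0.8])
        cons = [
            _consumer(float(rng.normal(-16, 1)), float(rng.normal(15, 1)), f"c{i}")
            for i in range(5)
        ]
        ll = ss.log_likelihood(p, s, cons, three_groups, post_tef_vib)
        mean, var = ss.mixture_moments(p, three_groups, post_tef_vib)
        total_sd = np.sqrt(var * s**2)
        want = sum(
            stats.norm.logpdf(c.d13C, mean[0], total_sd[0])
            + stats.norm.logpdf(c.d15N, mean[1], total_sd[1])
            for c in cons
        )
        assert ll == pytest.approx(want, abs=1e-10)

    def test_process_model_rejects_residual_scale(self, three_groups, post_tef_vib):
        with pytest.raises(ValueError):
            ss.log_likelihood(
                [1 / 3] * 3, [1.0, 1.0], [], three_groups, post_tef_vib, "process"
            )


class TestPriorFromDiet:
    def test_scat_weights(self):
        alpha = ss.prior_from_diet([1.4, 53.3, 40.6])
        assert alpha == pytest.approx([0.04407, 1.67786, 1.27807], abs=1e-4)
        assert alpha.sum() == pytest.approx(3.0)

    def test_equal_weights_uninformative(self):
        assert ss.prior_from_diet([2.0, 2.0, 2.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_normalized_weights_sum_to_k(self):
        alpha = ss.prior_from_diet([0.1, 0.2, 0.3, 0.4])
        assert alpha.sum() == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ss.prior_from_diet([0.0, 0.0])


class TestRunMcmc:
    def test_prior_recovery_uniform(self, three_groups, post_tef_vib):
        """With no consumers and Dirichlet(1,1,1), posterior means are 1/3."""
        cfg = ss.SIMMConfig(
            groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1, 1],
            seed=7, **SHORT,
        )
        post = ss.run_mcmc(cfg, [])
        assert post.draws.mean(axis=0) == pytest.approx([1 / 3] * 3, abs=0.02)

    def test_prior_recovery_scat_alpha(self, three_groups, post_tef_vib):
        alpha = ss.prior_from_diet([1.4, 53.3, 40.6])
        cfg = ss.SIMMConfig(
            groups=three_groups, tef=post_tef_vib, prior_alpha=alpha, seed=8, **SHORT
        )
        post = ss.run_mcmc(cfg, [])
        assert post.draws.mean(axis=0) == pytest.approx(alpha / alpha.sum(), abs=0.02)

    def test_draws_on_simplex(self, three_groups, post_tef_vib):
        cfg = ss.SIMMConfig(
            groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1, 1],
            chains=2, iterations=4000, burn_in=1000, thin=5, seed=0,
        )
        post = ss.run_mcmc(cfg, [])
        sums = post.draws.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-12
        assert (post.draws >= 0).all()

    def test_seed_reproducibility(self, three_groups, post_tef_vib, vib_consumers):
        kw = dict(
            groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1, 1],
            chains=2, iterations=3000, burn_in=1000, thin=5, seed=123,
        )
        a = ss.run_mcmc(ss.SIMMConfig(**kw), vib_consumers[:5])
        b = ss.run_mcmc(ss.SIMMConfig(**kw), vib_consumers[:5])
        assert np.array_equal(a.chain_draws, b.chain_draws)
        assert np.array_equal(a.chain_residual, b.chain_residual)

    def test_parameter_recovery_synthetic(self):
        """Posterior medians recover a known diet within ±0.05 with 25 well-
        separated-source consumers (moderate n keeps the runtime small)."""
        truth = np.array([0.2, 0.3, 0.5])
        cons = ss.gen_consumers(truth, WELL_SEPARATED, TIGHT_TEF, n=25, seed=5)
        cfg = ss.SIMMConfig(
            groups=WELL_SEPARATED, tef=TIGHT_TEF, prior_alpha=[1, 1, 1],
            seed=6, **SHORT,
        )
        post = ss.run_mcmc(cfg, cons)
        med = np.median(post.draws, axis=0)
        assert med == pytest.approx(truth, abs=0.05)

    def test_likelihood_dominates_prior_with_growing_n(self):
        """A strongly wrong prior washes out as consumers accumulate."""
        truth = np.array([0.2, 0.3, 0.5])
        wrong_alpha = ss.prior_from_diet([80.0, 15.0, 5.0])
        errs = []
        for n in (10, 100):
            cons = ss.gen_consumers(truth, WELL_SEPARATED, TIGHT_TEF, n=n, seed=n)
            cfg = ss.SIMMConfig(
                groups=WELL_SEPARATED, tef=TIGHT_TEF, prior_alpha=wrong_alpha,
                seed=n, **SHORT,
            )
            post = ss.run_mcmc(cfg, cons)
            errs.append(np.abs(np.median(post.draws, axis=0) - truth).max())
        assert errs[-1] < 0.05
        assert errs[-1] <= errs[0] + 0.01

    def test_label_permutation_equivariance(self, three_groups, post_tef_vib, vib_consumers):
        """Permuting group order permutes posterior summaries (within MC noise)."""
        kw = dict(tef=post_tef_vib, prior_alpha=[1, 1, 1], seed=3, **SHORT)
        a = ss.run_mcmc(ss.SIMMConfig(groups=three_groups, **kw), vib_consumers)
        perm = [2, 0, 1]
        b = ss.run_mcmc(
            ss.SIMMConfig(groups=[three_groups[i] for i in perm], **kw), vib_consumers
        )
        mean_a = a.draws.mean(axis=0)
        mean_b = b.draws.mean(axis=0)
        assert mean_b == pytest.approx(mean_a[perm], abs=0.03)

    def test_rhat_reported_for_all_parameters(self, three_groups, post_tef_vib):
        cfg = ss.SIMMConfig(
            groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1, 1],
            chains=2, iterations=3000, burn_in=1000, thin=5, seed=0,
        )
        post = ss.run_mcmc(cfg, [])
        assert set(post.rhat) == {
            "p[squid]", "p[sand lance]", "p[demersal fishes]",
            "residual_scale[d13C]", "residual_scale[d15N]",
        }

    def test_config_validation(self, three_groups, post_tef_vib):
        with pytest.raises(ValueError):
            ss.SIMMConfig(groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1])
        with pytest.raises(ValueError):
            ss.SIMMConfig(groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 0, 1])
        with pytest.raises(ValueError):
            ss.SIMMConfig(
                groups=three_groups, tef=post_tef_vib, prior_alpha=[1, 1, 1],
                iterations=100, burn_in=100,
            )


class TestSplitRhat:
    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        chains = rng.normal(size=(4, 400)) + rng.normal(size=(4, 1)) * 0.3
        mine = split_rhat(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values.item())
        # arviz rank-normalizes; agreement is approximate on near-normal draws
        assert mine == pytest.approx(theirs, abs=0.05)

    def test_identical_chains_near_one(self, rng):
        row = rng.normal(size=600)
        chains = np.tile(row, (3, 1))
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_large(self, rng):
        chains = np.stack([rng.normal(0, 0.1, 400), rng.normal(5, 0.1, 400)])
        assert split_rhat(chains) > 2.0


class TestSummarizePosterior:
    def _posterior(self, draws):
        return ss.DietPosterior(
            group_names=("a", "b", "c"),
            chain_draws=draws[None, :, :],
            chain_residual=None,
            rhat={},
            converged=True,
        )

    def test_constant_draws(self):
        draws = np.tile([0.2, 0.3, 0.5], (200, 1))
        s = ss.summarize_posterior(self._posterior(draws))
        assert np.allclose(s["mean"], s["median"], atol=1e-12)
        assert np.allclose(s["ci_2.5"], [20.0, 30.0, 50.0], atol=1e-12)
        assert np.allclose(s["ci_97.5"], [20.0, 30.0, 50.0], atol=1e-12)

    def test_beta_marginal_quantiles(self, rng):
        """Dirichlet(2,3,5) first component is Beta(2,8): sampled quantiles
        match the closed form within Monte-Carlo error."""
        draws = rng.dirichlet([2, 3, 5], size=20_000)
        s = ss.summarize_posterior(self._posterior(draws), percent=False)
        assert s.loc[0, "median"] == pytest.approx(stats.beta.ppf(0.5, 2, 8), abs=0.01)
        assert s.loc[0, "ci_2.5"] == pytest.approx(stats.beta.ppf(0.025, 2, 8), abs=0.01)
        assert s.loc[0, "ci_97.5"] == pytest.approx(stats.beta.ppf(0.975, 2, 8), abs=0.015)

    def test_too_few_draws_rejected(self):
        draws = np.tile([0.2, 0.3, 0.5], (50, 1))
        with pytest.raises(ValueError, match="too few"):
            ss.summarize_posterior(self._posterior(draws))
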