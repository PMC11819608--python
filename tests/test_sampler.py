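"""MCMC kernels against analytic, quadrature and grid oracles."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import gammaln

from isodex import (GeneData, MCMCConfig, SampleDesign,
                    allocate_latent_counts, gg_log_marginal, gibbs_beta,
                    gibbs_lambda, gibbs_nu, gibbs_tau, mh_update_U,
                    mh_update_shape, run_mcmc, sample_d)


class TestAllocateLatentCounts:
    def test_single_isoform_takes_all(self, rng):
        assert allocate_latent_counts(10, np.array([3.0]), rng).tolist() == [10]

    def test_counts_conserved_and_symmetric(self, rng):
        draws = np.array([
            allocate_latent_counts(10, np.array([2.0, 2.0]), rng)
            for _ in range(2000)])
        assert np.all(draws.sum(axis=1) == 10)
        assert draws[:, 0].mean() == pytest.approx(5.0, abs=0.15)

    def test_binomial_marginal(self, rng):
        """With rates (9, 1) the first-isoform count is Binomial(10, 0.9)."""
        n = 20000
        draws = np.array([
            allocate_latent_counts(10, np.array([9.0, 1.0]), rng)[0]
            for _ in range(n)])
        se = np.sqrt(10 * 0.9 * 0.1 / n)
        assert abs(draws.mean() - 9.0) < 3 * se

    def test_zero_rates_with_count_rejected(self, rng):
        with pytest.raises(ValueError):
            allocate_latent_counts(3, np.array([0.0, 0.0]), rng)


class TestConjugateKernels:
    def test_beta_posterior_parameters(self, rng):
        # alpha=1, lam=1, 20 latent reads, exposure 10 -> Gamma(21, 11)
        draws = gibbs_beta(np.full(50000, 20.0), np.full(50000, 10.0),
                           1.0, np.ones(50000), rng)
        assert draws.mean() == pytest.approx(21 / 11, rel=0.02)
        assert draws.var() == pytest.approx(21 / 11**2, rel=0.06)

    def test_beta_no_data_limit_is_prior(self, rng):
        draws = gibbs_beta(np.zeros(50000), np.full(50000, 1e-12),
                           2.0, np.full(50000, 3.0), rng)
        assert draws.mean() == pytest.approx(2 / 3, rel=0.03)

    def test_tau_zero_dispersion_draws_prior_gamma(self, rng):
        draws = np.array([
            gibbs_tau(np.zeros(4), np.ones(4, dtype=np.int8), 2.0, 3.0, rng)
            for _ in range(10000)])
        # Gamma(2 + 2, 3): mean 4/3
        se = np.sqrt(4 / 9 / draws.size)
        assert abs(draws.mean() - 4 / 3) < 4 * se
        ks = stats.kstest(draws, stats.gamma(4, scale=1 / 3).cdf)
        assert ks.pvalue > 0.01

    def test_lambda_shared_parameters_and_symmetry(self, rng):
        design = SampleDesign.from_sizes(2, 2)
        beta_t = np.array([1.0, 2.0, 1.5, 1.5])
        # d=0, alpha=2, alpha0=1, nu=1, sum beta=6 -> Gamma(9, 7)
        draws = np.array([
            gibbs_lambda(beta_t, design, 2.0, 1.0, 1.0, 0, rng)[0]
            for _ in range(20000)])
        assert draws.mean() == pytest.approx(9 / 7, rel=0.02)
        ks = stats.kstest(draws, stats.gamma(9, scale=1 / 7).cdf)
        assert ks.pvalue > 0.01
        # identical groups under d=1: lam1 and lam2 identically distributed
        pairs = np.array([
            gibbs_lambda(np.array([1.0, 2.0, 1.0, 2.0]), design,
                         2.0, 1.0, 1.0, 1, rng)
            for _ in range(20000)])
        ks2 = stats.ks_2samp(pairs[:, 0], pairs[:, 1])
        assert ks2.pvalue > 0.01

    def test_nu_conjugate_and_prior_limit(self, rng):
        draws = np.array([
            gibbs_nu(np.array([1.0, 2.0]), 1.0, 1.0, 1.0, rng)
            for _ in range(20000)])
        ks = stats.kstest(draws, stats.gamma(3, scale=1 / 4).cdf)
        assert ks.pvalue > 0.01
        prior = np.array([
            gibbs_nu(np.array([]), 1.0, 2.0, 5.0, rng) for _ in range(20000)])
        assert prior.mean() == pytest.approx(2 / 5, rel=0.05)


class TestSampleD:
    def test_likelihood_domination(self, rng):
        b1 = np.array([100.0, 101.0, 99.0])
        b2 = np.array([1.0, 1.01, 0.99])
        _, prob = sample_d(b1, b2, 1.0, 1.0, 1.0, 0.5, rng)
        assert prob > 0.99

    def test_prior_limit(self, rng):
        b1 = np.array([100.0, 101.0])
        b2 = np.array([1.0, 1.01])
        _, prob = sample_d(b1, b2, 1.0, 1.0, 1.0, 1e-12, rng)
        assert prob < 1e-6

    def test_matches_bruteforce_quadrature(self, rng):
        """Collapsed probability equals numeric integration over the group
        rates on a J1=J2=2, alpha=alpha0=nu=1 toy."""
        alpha = alpha0 = nu = 1.0
        pi1 = 0.5
        b1 = np.array([0.8, 1.9])
        b2 = np.array([3.1, 2.4])

        def lik(beta, lam):
            return np.prod(stats.gamma.pdf(beta, alpha, scale=1 / lam))

        def prior(lam):
            return stats.gamma.pdf(lam, alpha0, scale=1 / nu)

        m1 = integrate.dblquad(
            lambda l2, l1: lik(b1, l1) * prior(l1) * lik(b2, l2) * prior(l2),
            0, 60, 0, 60)[0]
        m0 = integrate.quad(
            lambda lam: lik(np.concatenate([b1, b2]), lam) * prior(lam),
            0, 60, limit=200)[0]
        expected = pi1 * m1 / (pi1 * m1 + (1 - pi1) * m0)
        _, prob = sample_d(b1, b2, alpha, alpha0, nu, pi1, rng)
        assert prob == pytest.approx(expected, rel=1e-4)

    def test_monotone_in_separation(self, rng):
        """More between-group mean separation at fixed spread never lowers
        the conditional differential probability."""
        spread = np.array([-0.1, 0.0, 0.1])
        probs = []
        for shift in [0.0, 0.5, 1.0, 2.0, 4.0]:
            b1 = 1.0 + spread
            b2 = 1.0 + shift + spread
            probs.append(sample_d(b1, b2, 2.0, 1.0, 1.0, 0.5, rng)[1])
        assert np.all(np.diff(probs) >= -1e-12)


class TestMhUpdateU:
    def test_sum_conserved_to_machine_precision(self, rng):
        U = np.array([0.2, -0.1, -0.1, 0.0])
        s = np.ones(4, dtype=np.int8)
        y = np.abs(rng.poisson(5.0, size=(4, 3))).astype(float)
        x = np.full((4, 3), 2.0)
        new, acc = mh_update_U(U, s, y, x, np.array([1.0, 1.0, 1.0]),
                               1.0, 0.3, rng)
        assert abs(new.sum() - U.sum()) < 1e-12
        assert acc.size == 4

    def test_fewer_than_two_regions_noop(self, rng):
        new, acc = mh_update_U(np.array([0.5]), np.array([1]),
                               np.zeros((1, 2)), np.ones((1, 2)),
                               np.array([1.0, 1.0]), 1.0, 0.2, rng)
        assert new.tolist() == [0.0] and acc.size == 0

    def test_large_tau_concentrates_near_zero(self, rng):
        y = rng.poisson(20.0, size=(3, 4)).astype(float)
        x = np.full((3, 4), 5.0)
        beta = np.full(4, 1.0)
        s = np.ones(3, dtype=np.int8)
        samples = {}
        for tau in (0.5, 1e4):
            U = np.zeros(3)
            traj = []
            for _ in range(800):
                U, _ = mh_update_U(U, s, y, x, beta, tau, 0.3, rng)
                traj.append(np.abs(U).mean())
            samples[tau] = np.mean(traj[200:])
        assert samples[1e4] < samples[0.5]

    def test_two_region_equilibrium_matches_grid_target(self, rng):
        """Stationary law of U1 (= -U2) matches the grid-normalized target
        built from the Poisson likelihood of the region totals + prior."""
        y = np.array([[30.0, 24.0], [12.0, 18.0]])
        x = np.full((2, 2), 3.0)
        beta = np.array([2.0, 2.5])
        tau = 2.0
        s = np.ones(2, dtype=np.int8)

        def log_target(u):
            total = -tau * u**2  # both entries contribute tau*u^2/2
            for j in range(2):
                r1 = x[0, j] * beta[j] * np.exp(u)
                r2 = x[1, j] * beta[j] * np.exp(-u)
                total += y[0, j] * np.log(r1) - r1
                total += y[1, j] * np.log(r2) - r2
            return total

        grid = np.linspace(-1.5, 1.5, 3001)
        dens = np.exp(log_target(grid) - log_target(grid).max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]

        U = np.zeros(2)
        kept = []
        for it in range(6000):
            U, _ = mh_update_U(U, s, y, x, beta, tau, 0.25, rng)
            if it >= 1000 and it % 5 == 0:
                kept.append(U[0])
        ks = stats.ks_1samp(np.array(kept), lambda v: np.interp(v, grid, cdf))
        assert ks.pvalue > 0.01


class TestMhUpdateShape:
    def test_tiny_scale_high_acceptance(self, rng):
        accepts = [mh_update_shape(2.0, lambda a: -a, 1e-6, rng)[1]
                   for _ in range(200)]
        assert np.mean(accepts) > 0.95

    def test_nonfinite_target_rejected(self, rng):
        with pytest.raises(ValueError):
            mh_update_shape(1.0, lambda a: np.nan, 0.3, rng)

    def test_recovers_shape_posterior(self, rng):
        """Chain over alpha given many Gamma(3, 1) observations concentrates
        near the grid-posterior mode."""
        data = rng.gamma(3.0, 1.0, size=400)
        s_log = float(np.log(data).sum())
        s_sum = float(data.sum())
        n = data.size

        def log_target(a):
            return ((a - 1) * s_log - s_sum - n * gammaln(a)
                    + (0.01 - 1) * np.log(a) - 0.01 * a)

        grid = np.linspace(1.5, 5.0, 2000)
        mode = grid[np.argmax([log_target(a) for a in grid])]
        cur = 1.0
        kept = []
        for it in range(4000):
            cur, _ = mh_update_shape(cur, log_target, 0.1, rng)
            if it > 1000:
                kept.append(cur)
        assert np.mean(kept) == pytest.approx(mode, abs=0.4)
        assert abs(mode - 3.0) < 0.5

    def test_stationary_matches_grid_density(self, rng):
        """Detailed balance: empirical law matches the grid-normalized target."""
        def log_target(a):
            return stats.gamma.logpdf(a, 3.0, scale=0.5)

        grid = np.linspace(1e-3, 10, 5001)
        dens = np.exp([log_target(a) for a in grid])
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        cur = 1.0
        kept = []
        for it in range(20000):
            cur, _ = mh_update_shape(cur, log_target, 0.5, rng)
            if it > 2000 and it % 4 == 0:
                kept.append(cur)
        ks = stats.ks_1samp(np.array(kept), lambda v: np.interp(v, grid, cdf))
        assert ks.pvalue > 0.01


class TestRunMcmc:
    def _tiny_dataset(self, seed=5):
        from isodex import SimulationConfig, simulate_dataset
        return simulate_dataset(SimulationConfig(n_genes=4, j1=3, j2=3,
                                                 seed=seed))

    def test_seeded_determinism(self):
        ds = self._tiny_dataset()
        cfg = MCMCConfig(n_iter=60, burn_in=30, seed=7)
        a = run_mcmc(ds.gene_data(), ds.design, cfg)
        b = run_mcmc(ds.gene_data(), ds.design, cfg)
        assert a.to_table().equals(b.to_table())
        assert a.alpha_hat == b.alpha_hat and a.nu_hat == b.nu_hat
        for gid in a.p:
            assert np.array_equal(a.U_hat[gid], b.U_hat[gid])

    def test_invariants_hold_throughout(self):
        ds = self._tiny_dataset(seed=9)
        cfg = MCMCConfig(n_iter=40, burn_in=20, seed=3, check_invariants=True)
        summary = run_mcmc(ds.gene_data(), ds.design, cfg)
        for gid in summary.p:
            assert np.all((summary.p[gid] >= 0) & (summary.p[gid] <= 1))
            assert np.all(summary.beta_hat[gid] > 0)
            assert np.all(summary.tau_hat[gid] > 0)
        for v in summary.acceptance_rates.values():
            assert 0.0 <= v <= 1.0

    def test_zero_count_gene_flagged(self):
        design = SampleDesign.from_sizes(2, 2)
        gd = GeneData("gZ", ["gZ.t1"], np.ones((1, 2), dtype=np.int8),
                      np.zeros((2, 4), dtype=np.int64), np.full((2, 4), 1.0))
        summary = run_mcmc([gd], design, MCMCConfig(n_iter=20, burn_in=10,
                                                    seed=1, pi1=0.4))
        assert summary.not_estimable["gZ"][0]
        assert summary.p["gZ"][0] == pytest.approx(0.4)

    def test_single_isoform_beta_tracks_likelihood(self):
        """At deep counts the chain's abundance posterior mean approaches the
        maximum-likelihood FPKM y/x (priors become negligible)."""
        rng = np.random.default_rng(0)
        design = SampleDesign.from_sizes(2, 2)
        y = rng.poisson(120.0, size=(1, 4)).astype(np.int64)
        x = np.full((1, 4), 6.0)
        gd = GeneData("g", ["g.t1"], np.ones((1, 1), dtype=np.int8), y, x)
        # single region -> U pinned to 0, so exposure is exactly x
        summary = run_mcmc([gd], design,
                           MCMCConfig(n_iter=3000, burn_in=1000, seed=2))
        expected = y.sum(axis=0) / x[0]
        assert np.allclose(summary.beta_hat["g"][0], expected, rtol=0.1)
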