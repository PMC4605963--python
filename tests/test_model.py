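import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import _oracles as oracles
from bayesmig import model as hm
from bayesmig.data_io import MigrationDataset
from bayesmig.model import CountryParams, HyperParams, ModelParams


def make_data(rates, pops=None):
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    C, T = rates.shape
    pops = np.full((C, T), 1e6) if pops is None else pops
    return MigrationDataset(
        country_ids=[f"X{i}" for i in range(C)],
        period_starts=1950 + 5 * np.arange(T),
        rates=rates,
        populations=pops,
    )


def make_state(country_params, hyper=None):
    hyper = hyper or HyperParams(lam=0.0, tau=1.0, a=3.0, b=10.0)
    return ModelParams(countries=list(country_params), hyper=hyper)


class TestLogLikelihood:
    def test_single_transition_hand_value(self):
        # r = (0, 1), mu=0, phi=0.5, sigma2=1: eps = 1 - 0.5*0 = 1
        # log N(1; 0, 1) = -log(2 pi)/2 - 1/2
        state = make_state([CountryParams(0.0, 0.5, 1.0)])
        data = make_data([0.0, 1.0])
        expected = -0.5 * math.log(2 * math.pi) - 0.5
        assert hm.log_likelihood(state, data) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.41894, abs=5e-6)

    def test_phi_zero_reduces_to_iid(self, rng):
        r = rng.normal(1.0, 2.0, size=7)
        state = make_state([CountryParams(1.3, 1e-300, 2.5)])
        data = make_data(r)
        got = hm.log_likelihood(state, data)
        want = float(np.sum(stats.norm.logpdf(r[1:], 1.3, math.sqrt(2.5))))
        assert got == pytest.approx(want, rel=1e-9)

    def test_additivity_over_countries(self, rng):
        r1 = rng.normal(0, 3, size=5)
        r2 = rng.normal(0, 3, size=5)
        cp1 = CountryParams(0.5, 0.4, 2.0)
        cp2 = CountryParams(-1.0, 0.7, 1.0)
        both = hm.log_likelihood(
            make_state([cp1, cp2]), make_data(np.vstack([r1, r2]))
        )
        solo = hm.log_likelihood(make_state([cp1]), make_data(r1)) + hm.log_likelihood(
            make_state([cp2]), make_data(r2)
        )
        assert both == pytest.approx(solo, rel=1e-12)

    def test_single_observation_contributes_zero(self):
        state = make_state([CountryParams(0.0, 0.5, 1.0)])
        data = make_data(np.array([[np.nan, np.nan, np.nan, 1.0]]))
        assert hm.log_likelihood(state, data) == 0.0


class TestLogPrior:
    def test_a_outside_support(self):
        state = make_state(
            [CountryParams(0.0, 0.5, 1.0)], HyperParams(0.0, 1.0, 0.5, 10.0)
        )
        assert hm.log_prior(state) == -math.inf

    def test_phi_outside_support(self):
        state = make_state([CountryParams(0.0, 1.2, 1.0)])
        assert hm.log_prior(state) == -math.inf

    def test_b_above_conditional_bound(self):
        state = make_state(
            [CountryParams(0.0, 0.5, 1.0)], HyperParams(0.0, 1.0, 1.5, 60.0)
        )
        assert hm.log_prior(state) == -math.inf  # 60 >= 100*(1.5-1)

    def test_interior_matches_termwise_scipy_sum(self, rng):
        for _ in range(5):
            state, _ = oracles.random_small_state(rng)
            h = state.hyper
            want = (
                stats.uniform.logpdf(h.a, 1, 9)
                + stats.uniform.logpdf(h.b, 0, 100 * (h.a - 1))
                + stats.uniform.logpdf(h.lam, -100, 200)
                + stats.uniform.logpdf(h.tau, 0, 100)
            )
            for cp in state.countries:
                want += stats.norm.logpdf(cp.mu, h.lam, h.tau)
                want += stats.invgamma.logpdf(cp.sigma2, h.a, scale=h.b)
                want += stats.uniform.logpdf(cp.phi, 0, 1)
            assert hm.log_prior(state) == pytest.approx(float(want), rel=1e-10)


class TestCondMu:
    def test_flat_prior_limit_recovers_sample_mean(self, rng):
        r = rng.normal(2.0, 1.0, size=9)
        state = make_state(
            [CountryParams(0.0, 1e-12, 1.0)], HyperParams(0.0, 99.0, 3.0, 10.0)
        )
        cond = hm.cond_mu(0, state, make_data(r))
        assert cond.mean == pytest.approx(np.mean(r[1:]), rel=1e-3)

    def test_grid_oracle_specific_case(self):
        state = make_state(
            [CountryParams(0.0, 0.5, 1.0)], HyperParams(0.0, 1.0, 3.0, 10.0)
        )
        data = make_data([0.0, 1.0, 2.0])
        cond = hm.cond_mu(0, state, data)
        om, ov = oracles.posterior_moments_mu(state, data, 0)
        assert cond.mean == pytest.approx(om, rel=1e-6, abs=1e-9)
        assert cond.var == pytest.approx(ov, rel=1e-6)

    def test_phi_to_one_returns_prior(self):
        state = make_state(
            [CountryParams(0.0, 1.0 - 1e-15, 1.0)], HyperParams(0.7, 2.0, 3.0, 10.0)
        )
        cond = hm.cond_mu(0, state, make_data([0.0, 1.0, 2.0]))
        assert cond.mean == pytest.approx(0.7, abs=1e-9)
        assert cond.var == pytest.approx(4.0, rel=1e-9)

    def test_no_transitions_returns_prior(self):
        state = make_state([CountryParams(0.0, 0.5, 1.0)])
        data = make_data(np.array([[np.nan, 1.0]]))
        cond = hm.cond_mu(0, state, data)
        assert (cond.mean, cond.var) == (0.0, 1.0)


class TestCondPhi:
    def test_noise_free_regression_mean(self):
        # z_t = 0.5 x_t exactly: r - mu follows deviations halving each step
        mu = 1.0
        r = mu + 8.0 * 0.5 ** np.arange(5)
        state = make_state([CountryParams(mu, 0.3, 1.0)])
        cond = hm.cond_phi(0, state, make_data(r))
        assert cond.mean == pytest.approx(0.5, rel=1e-12)

    def test_single_transition_hand_value(self):
        # x=2, z=1, sigma2=4 -> mean 0.5, var 1.0
        state = make_state([CountryParams(0.0, 0.3, 4.0)])
        cond = hm.cond_phi(0, state, make_data([2.0, 1.0]))
        assert (cond.mean, cond.var) == (0.5, 1.0)
        assert (cond.lower, cond.upper) == (0.0, 1.0)

    def test_degenerate_design_gives_uniform(self):
        state = make_state([CountryParams(1.0, 0.3, 1.0)])
        # all x_t = r_{t-1} - mu = 0
        cond = hm.cond_phi(0, state, make_data([1.0, 1.0, 1.0]))
        assert cond.flat


class TestCondSigma2:
    def test_zero_residuals(self):
        mu, phi = 0.0, 0.5
        r = 4.0 * phi ** np.arange(4)  # exact AR(1) path, no noise
        state = make_state([CountryParams(mu, phi, 1.0)])
        cond = hm.cond_sigma2(0, state, make_data(r))
        assert cond.shape == pytest.approx(3.0 + 3 / 2)
        assert cond.rate == pytest.approx(10.0, abs=1e-20)

    def test_single_residual_hand_value(self):
        state = make_state([CountryParams(0.0, 1e-300, 1.0)])
        cond = hm.cond_sigma2(0, state, make_data([0.0, 1.0]))
        assert cond.shape == pytest.approx(3.5)  # a + 1/2
        assert cond.rate == pytest.approx(10.5)  # b + 1/2

    def test_no_data_returns_prior(self):
        state = make_state([CountryParams(0.0, 0.5, 1.0)])
        data = make_data(np.array([[np.nan, 2.0]]))
        cond = hm.cond_sigma2(0, state, data)
        assert (cond.shape, cond.rate) == (3.0, 10.0)
        # prior mean b/(a-1)
        assert cond.rate / (cond.shape - 1) == pytest.approx(5.0)


class TestCondB:
    def test_kernel_algebra_c1(self):
        state = make_state(
            [CountryParams(0.0, 0.5, 1.0)], HyperParams(0.0, 1.0, 2.0, 10.0)
        )
        cond = hm.cond_b(state)
        assert cond.shape == pytest.approx(3.0)  # C*a + 1
        assert cond.rate == pytest.approx(1.0)  # sum 1/sigma2
        assert cond.upper == pytest.approx(100.0)

    def test_untruncated_mode(self, rng):
        state, _ = oracles.random_small_state(rng, C=3)
        cond = hm.cond_b(state)
        mode = (cond.shape - 1) / cond.rate  # gamma mode
        Ca = state.n_countries * state.hyper.a
        assert mode == pytest.approx(Ca / np.sum(1.0 / state.sigma2_vector()))

    def test_truncation_bound_exact(self, rng):
        state, _ = oracles.random_small_state(rng)
        assert hm.cond_b(state).upper == 100.0 * (state.hyper.a - 1.0)


class TestCondLambda:
    def test_symmetric_two_country_case(self):
        state = make_state(
            [CountryParams(-1.0, 0.5, 1.0), CountryParams(1.0, 0.5, 1.0)],
            HyperParams(0.3, 1.0, 3.0, 10.0),
        )
        cond = hm.cond_lambda(state)
        assert cond.mean == pytest.approx(0.0)
        assert cond.var == pytest.approx(0.5)
        assert (cond.lower, cond.upper) == (-100.0, 100.0)

    def test_no_countries_flat(self):
        state = ModelParams(countries=[], hyper=HyperParams(0.0, 1.0, 3.0, 10.0))
        assert hm.cond_lambda(state).flat


class TestHyperKernels:
    def test_tau_outside_support(self, rng):
        state, _ = oracles.random_small_state(rng)
        assert hm.log_cond_tau(-1.0, state) == -math.inf
        assert hm.log_cond_tau(101.0, state) == -math.inf

    def test_a_joint_support_with_b(self, rng):
        state, _ = oracles.random_small_state(rng)
        state.hyper.b = 30.0
        # b >= 100(a-1)  <=>  a <= 1.3
        assert hm.log_cond_a(1.25, state) == -math.inf
        assert np.isfinite(hm.log_cond_a(1.5, state))

    def test_kernels_match_density_product_on_random_states(self, rng):
        # kernel differences must equal full log-prior differences
        for _ in range(5):
            state, _ = oracles.random_small_state(rng)
            s2 = ModelParams(
                countries=[replace(cp) for cp in state.countries],
                hyper=replace(state.hyper),
            )
            t1, t2 = 1.5, 4.0
            state.hyper.tau, s2.hyper.tau = t1, t2
            dk = hm.log_cond_tau(t1, state) - hm.log_cond_tau(t2, s2)
            dp = hm.log_prior(state) - hm.log_prior(s2)
            assert dk == pytest.approx(dp, rel=1e-9, abs=1e-9)

            a1, a2 = 3.1, 5.7
            state.hyper.tau = s2.hyper.tau = 2.0
            state.hyper.a, s2.hyper.a = a1, a2
            dk = hm.log_cond_a(a1, state) - hm.log_cond_a(a2, s2)
            dp = hm.log_prior(state) - hm.log_prior(s2)
            assert dk == pytest.approx(dp, rel=1e-9, abs=1e-9)


@pytest.fixture(scope="module")
def states():
    rng = np.random.default_rng(777)
    return [oracles.random_small_state(rng) for _ in range(5)]


class TestGridOracleProperty:
    """Every closed-form conditional matches grid integration of
    exp(log_likelihood + log_prior) in its coordinate."""

    def test_cond_mu(self, states):
        for state, data in states:
            cond = hm.cond_mu(0, state, data)
            om, ov = oracles.posterior_moments_mu(state, data, 0)
            assert cond.mean == pytest.approx(om, rel=1e-6, abs=1e-8)
            assert cond.var == pytest.approx(ov, rel=1e-6)

    def test_cond_phi(self, states):
        for state, data in states:
            cond = hm.cond_phi(0, state, data)
            cm, cv = oracles.truncnorm_moments(
                cond.mean, cond.var, cond.lower, cond.upper
            )
            om, ov = oracles.posterior_moments_phi(state, data, 0)
            assert cm == pytest.approx(om, rel=1e-6, abs=1e-8)
            assert cv == pytest.approx(ov, rel=1e-6, abs=1e-10)

    def test_cond_sigma2(self, states):
        for state, data in states:
            cond = hm.cond_sigma2(0, state, data)
            cm, cv = oracles.invgamma_moments(cond.shape, cond.rate)
            om, ov = oracles.posterior_moments_sigma2(state, data, 0)
            assert cm == pytest.approx(om, rel=1e-6)
            assert cv == pytest.approx(ov, rel=1e-6)

    def test_cond_b(self, states):
        for state, data in states:
            cond = hm.cond_b(state)
            cm, cv = oracles.truncgamma_moments(cond.shape, cond.rate, cond.upper)
            om, ov = oracles.posterior_moments_b(state, data)
            assert cm == pytest.approx(om, rel=1e-6)
            assert cv == pytest.approx(ov, rel=1e-6)

    def test_cond_lambda(self, states):
        for state, data in states:
            cond = hm.cond_lambda(state)
            cm, cv = oracles.truncnorm_moments(
                cond.mean, cond.var, cond.lower, cond.upper
            )
            om, ov = oracles.posterior_moments_lambda(state, data)
            assert cm == pytest.approx(om, rel=1e-6, abs=1e-8)
            assert cv == pytest.approx(ov, rel=1e-6)


def test_posterior_invariant_under_country_permutation(rng):
    state, data = oracles.random_small_state(rng, C=3, T=4)
    perm = [2, 0, 1]
    state_p = ModelParams(
        countries=[replace(state.countries[i]) for i in perm], hyper=replace(state.hyper)
    )
    data_p = MigrationDataset(
        country_ids=[data.country_ids[i] for i in perm],
        period_starts=data.period_starts,
        rates=data.rates[perm],
        populations=data.populations[perm],
    )
    before = hm.log_likelihood(state, data) + hm.log_prior(state)
    after = hm.log_likelihood(state_p, data_p) + hm.log_prior(state_p)
    assert after == pytest.approx(before, rel=1e-12)
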