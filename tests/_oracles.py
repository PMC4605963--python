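"""Independent numerical oracles used by the unit and acceptance tests.

The central one integrates exp(log_likelihood + log_prior) over a fine
grid in a single coordinate (all other parameters held fixed) and returns
the mean and variance of the normalized density.  It never calls the
closed-form conditionals it is used to check.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from scipy import stats
from scipy.integrate import simpson

from bayesmig import model as hm
from bayesmig.model import CountryParams, HyperParams, ModelParams


def _clone(state: ModelParams) -> ModelParams:
    return ModelParams(
        countries=[replace(cp) for cp in state.countries],
        hyper=replace(state.hyper),
    )


def _log_post(state, data):
    return hm.log_likelihood(state, data) + hm.log_prior(state)


def grid_moments(logpost, grid, jacobian=None):
    """Mean/variance of the density exp(logpost(x)) on the grid.

    ``jacobian`` multiplies the integrand (for change-of-variable grids);
    the grid itself holds the original-coordinate values.
    """
    logs = np.array([logpost(x) for x in grid])
    logs -= logs.max()
    dens = np.exp(logs)
    if jacobian is not None:
        dens = dens * jacobian
    z = simpson(dens, x=np.arange(len(grid)))
    # integrate in index space against the (possibly transformed) grid:
    # caller supplies uniformly spaced transformed coordinates via jacobian.
    mean = simpson(dens * grid, x=np.arange(len(grid))) / z
    second = simpson(dens * grid * grid, x=np.arange(len(grid))) / z
    return float(mean), float(second - mean * mean)


def posterior_moments_mu(state, data, c, n=40_001, span=12.0):
    base = _clone(state)

    def logpost(x):
        base.countries[c].mu = x
        return _log_post(base, data)

    # crude center/scale from a coarse scan, then a fine grid
    coarse = np.linspace(state.countries[c].mu - 50, state.countries[c].mu + 50, 2001)
    lv = np.array([logpost(x) for x in coarse])
    center = coarse[lv.argmax()]
    curv = np.gradient(np.gradient(lv, coarse), coarse)
    sd = 1.0 / math.sqrt(max(-curv[lv.argmax()], 1e-6))
    grid = np.linspace(center - span * sd, center + span * sd, n)
    return grid_moments(logpost, grid)


def posterior_moments_phi(state, data, c, n=40_001):
    base = _clone(state)

    def logpost(x):
        base.countries[c].phi = x
        return _log_post(base, data)

    eps = 1e-9
    grid = np.linspace(eps, 1.0 - eps, n)
    return grid_moments(logpost, grid)


def posterior_moments_sigma2(state, data, c, n=40_001):
    base = _clone(state)

    def logpost_u(u):
        base.countries[c].sigma2 = math.exp(u)
        return _log_post(base, data) + u  # Jacobian of x = e^u

    # locate the mode in log space, then integrate on a wide log grid
    coarse = np.linspace(math.log(1e-6), math.log(1e6), 4001)
    lv = np.array([logpost_u(u) for u in coarse])
    center = coarse[lv.argmax()]
    grid_u = np.linspace(center - 30.0, center + 30.0, n)
    logs = np.array([logpost_u(u) for u in grid_u])
    logs -= logs.max()
    dens = np.exp(logs)
    x = np.exp(grid_u)
    z = simpson(dens, x=grid_u)
    mean = simpson(dens * x, x=grid_u) / z
    second = simpson(dens * x * x, x=grid_u) / z
    return float(mean), float(second - mean * mean)


def posterior_moments_b(state, data, n=40_001):
    base = _clone(state)
    upper = hm.B_UPPER_FACTOR * (state.hyper.a - 1.0)

    def logpost(x):
        base.hyper.b = x
        return _log_post(base, data)

    eps = upper * 1e-9
    grid = np.linspace(eps, upper - eps, n)
    logs = np.array([logpost(x) for x in grid])
    logs -= logs.max()
    dens = np.exp(logs)
    z = simpson(dens, x=grid)
    mean = simpson(dens * grid, x=grid) / z
    second = simpson(dens * grid * grid, x=grid) / z
    return float(mean), float(second - mean * mean)


def posterior_moments_lambda(state, data, n=40_001, span=12.0):
    base = _clone(state)

    def logpost(x):
        base.hyper.lam = x
        return _log_post(base, data)

    mu = np.array([cp.mu for cp in state.countries])
    center = mu.mean() if mu.size else 0.0
    sd = state.hyper.tau / math.sqrt(max(len(state.countries), 1))
    lo = max(-100.0 + 1e-9, center - span * sd)
    hi = min(100.0 - 1e-9, center + span * sd)
    grid = np.linspace(lo, hi, n)
    logs = np.array([logpost(x) for x in grid])
    logs -= logs.max()
    dens = np.exp(logs)
    z = simpson(dens, x=grid)
    mean = simpson(dens * grid, x=grid) / z
    second = simpson(dens * grid * grid, x=grid) / z
    return float(mean), float(second - mean * mean)


# -- closed-form moments of the distributions the conditionals return ------

def truncnorm_moments(mean, var, lower, upper):
    sd = math.sqrt(var)
    a, bnd = (lower - mean) / sd, (upper - mean) / sd
    m = stats.truncnorm.mean(a, bnd, loc=mean, scale=sd)
    v = stats.truncnorm.var(a, bnd, loc=mean, scale=sd)
    return float(m), float(v)


def invgamma_moments(shape, rate):
    if shape <= 2:
        raise ValueError("variance undefined for shape <= 2")
    mean = rate / (shape - 1.0)
    var = rate * rate / ((shape - 1.0) ** 2 * (shape - 2.0))
    return mean, var


def truncgamma_moments(shape, rate, upper):
    from scipy.special import gammainc

    z0 = gammainc(shape, upper * rate)
    m1 = (shape / rate) * gammainc(shape + 1.0, upper * rate) / z0
    m2 = (shape * (shape + 1.0) / rate**2) * gammainc(shape + 2.0, upper * rate) / z0
    return float(m1), float(m2 - m1 * m1)


def random_small_state(rng, C=None, T=None):
    """A randomized interior model state plus matching synthetic data."""
    from bayesmig.data_io import MigrationDataset

    C = C if C is not None else int(rng.integers(1, 4))
    T = T if T is not None else int(rng.integers(3, 6))
    countries = [
        CountryParams(
            mu=float(rng.normal(0, 2)),
            phi=float(rng.uniform(0.1, 0.9)),
            sigma2=float(rng.uniform(0.5, 5.0)),
        )
        for _ in range(C)
    ]
    a = float(rng.uniform(3.0, 6.0))
    hyper = HyperParams(
        lam=float(rng.uniform(-3, 3)),
        tau=float(rng.uniform(1.0, 5.0)),
        a=a,
        b=float(rng.uniform(5.0, min(50.0, 100.0 * (a - 1) - 1.0))),
    )
    state = ModelParams(countries=countries, hyper=hyper)
    rates = np.empty((C, T))
    for c, cp in enumerate(countries):
        rates[c, 0] = rng.normal(cp.mu, 2.0)
        for t in range(1, T):
            rates[c, t] = cp.mu + cp.phi * (rates[c, t - 1] - cp.mu) + rng.normal(
                0, math.sqrt(cp.sigma2)
            )
    pops = rng.uniform(1e5, 1e7, size=(C, T))
    data = MigrationDataset(
        country_ids=[f"X{i}" for i in range(C)],
        period_starts=1950 + 5 * np.arange(T),
        rates=rates,
        populations=pops,
    )
    return state, data
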