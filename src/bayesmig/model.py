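"""Three-level hierarchical AR(1) model for net migration rates.

Level 1 (per country c, periods t = 2..T):

    (r[c,t] - mu_c) = phi_c * (r[c,t-1] - mu_c) + eps[c,t],
    eps[c,t] ~ N(0, sigma2_c) independently.

Level 2: phi_c ~ U(0,1);  mu_c ~ N(lam, tau^2);  sigma2_c ~ IG(a, b).

Level 3: a ~ U(1,10);  b|a ~ U(0, 100(a-1));  lam ~ U(-100,100);
tau ~ U(0,100).

The likelihood conditions on the first observation of each country
(transitions only, no stationary-distribution term).  Countries with fewer
than two observed periods contribute nothing to the likelihood and draw
their parameters purely from the hierarchy.

All full conditionals below are exact closed forms of the corresponding
coordinate of exp(log_likelihood + log_prior); tests verify them against a
grid-integration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .data_io import MigrationDataset

__all__ = [
    "CountryParams",
    "HyperParams",
    "ModelParams",
    "NormalCond",
    "TruncNormalCond",
    "InvGammaCond",
    "TruncGammaCond",
    "log_likelihood",
    "log_prior",
    "cond_mu",
    "cond_phi",
    "cond_sigma2",
    "cond_b",
    "cond_lambda",
    "log_cond_tau",
    "log_cond_a",
]

_LOG_2PI = math.log(2.0 * math.pi)

# Printed prior supports.
PHI_BOUNDS = (0.0, 1.0)
A_BOUNDS = (1.0, 10.0)
LAMBDA_BOUNDS = (-100.0, 100.0)
TAU_BOUNDS = (0.0, 100.0)
B_UPPER_FACTOR = 100.0  # b | a ~ U(0, 100 * (a - 1))


@dataclass
class CountryParams:
    """AR(1) parameters for one country: long-run mean, persistence, noise."""

    mu: float
    phi: float
    sigma2: float

    def validate(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (PHI_BOUNDS[0] < self.phi < PHI_BOUNDS[1]):
            raise ValueError(f"phi must lie in (0,1), got {self.phi}")
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


@dataclass
class HyperParams:
    """Hyperparameters: mu_c ~ N(lam, tau^2), sigma2_c ~ IG(a, b)."""

    lam: float
    tau: float
    a: float
    b: float

    def validate(self) -> None:
        if not (LAMBDA_BOUNDS[0] < self.lam < LAMBDA_BOUNDS[1]):
            raise ValueError(f"lam must lie in (-100,100), got {self.lam}")
        if not (TAU_BOUNDS[0] < self.tau < TAU_BOUNDS[1]):
            raise ValueError(f"tau must lie in (0,100), got {self.tau}")
        if not (A_BOUNDS[0] < self.a < A_BOUNDS[1]):
            raise ValueError(f"a must lie in (1,10), got {self.a}")
        if not (0.0 < self.b < B_UPPER_FACTOR * (self.a - 1.0)):
            raise ValueError(
                f"b must lie in (0, 100(a-1)) = (0, {B_UPPER_FACTOR * (self.a - 1)}),"
                f" got {self.b}"
            )


@dataclass
class ModelParams:
    """Full parameter state: one CountryParams per country plus hypers."""

    countries: list[CountryParams] = field(default_factory=list)
    hyper: HyperParams = None

    def validate(self) -> None:
        for cp in self.countries:
            cp.validate()
        self.hyper.validate()

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    def mu_vector(self) -> np.ndarray:
        return np.array([cp.mu for cp in self.countries])

    def phi_vector(self) -> np.ndarray:
        return np.array([cp.phi for cp in self.countries])

    def sigma2_vector(self) -> np.ndarray:
        return np.array([cp.sigma2 for cp in self.countries])


class NormalCond(NamedTuple):
    mean: float
    var: float


class TruncNormalCond(NamedTuple):
    mean: float
    var: float
    lower: float
    upper: float
    #: True when data carry no information and the conditional is the flat prior.
    flat: bool = False


class InvGammaCond(NamedTuple):
    shape: float
    rate: float


class TruncGammaCond(NamedTuple):
    shape: float
    rate: float
    upper: float


def _transitions(data: MigrationDataset, c: int):
    """(previous, current) rate pairs for the observed series of country c."""
    r = data.observed_rates(c)
    return r[:-1], r[1:]


def log_likelihood(params: ModelParams, data: MigrationDataset) -> float:
    """AR(1) transition log likelihood summed over countries.

    Conditions on each country's first observation; countries with fewer
    than two observations contribute zero.
    """
    total = 0.0
    for c, cp in enumerate(params.countries):
        prev, curr = _transitions(data, c)
        if prev.size == 0:
            continue
        eps = (curr - cp.mu) - cp.phi * (prev - cp.mu)
        total += -0.5 * prev.size * (_LOG_2PI + math.log(cp.sigma2))
        total += -0.5 * float(np.sum(eps * eps)) / cp.sigma2
    return total


def log_prior(params: ModelParams) -> float:
    """Joint log density of Levels 2 and 3; -inf outside any support."""
    h = params.hyper
    if not (A_BOUNDS[0] < h.a < A_BOUNDS[1]):
        return -math.inf
    b_upper = B_UPPER_FACTOR * (h.a - 1.0)
    if not (0.0 < h.b < b_upper):
        return -math.inf
    if not (LAMBDA_BOUNDS[0] < h.lam < LAMBDA_BOUNDS[1]):
        return -math.inf
    if not (TAU_BOUNDS[0] < h.tau < TAU_BOUNDS[1]):
        return -math.inf

    # Level 3: independent/conditional uniforms.
    total = -math.log(A_BOUNDS[1] - A_BOUNDS[0])
    total += -math.log(b_upper)
    total += -math.log(LAMBDA_BOUNDS[1] - LAMBDA_BOUNDS[0])
    total += -math.log(TAU_BOUNDS[1] - TAU_BOUNDS[0])

    # Level 2 per country.
    tau2 = h.tau * h.tau
    log_ig_norm = h.a * math.log(h.b) - math.lgamma(h.a)
    for cp in params.countries:
        if not (PHI_BOUNDS[0] < cp.phi < PHI_BOUNDS[1]):
            return -math.inf
        if not (np.isfinite(cp.sigma2) and cp.sigma2 > 0):
            return -math.inf
        # phi ~ U(0,1): log density 0
        total += -0.5 * (_LOG_2PI + math.log(tau2)) - (cp.mu - h.lam) ** 2 / (
            2.0 * tau2
        )
        total += log_ig_norm - (h.a + 1.0) * math.log(cp.sigma2) - h.b / cp.sigma2
    return total


def cond_mu(c: int, state: ModelParams, data: MigrationDataset) -> NormalCond:
    """Full conditional of mu_c: conjugate normal.

    With k = 1 - phi_c and d_t = r_t - phi_c r_{t-1}, the residual is
    eps_t = d_t - k mu, so the conditional has
    precision = (T-1) k^2 / sigma2 + 1/tau^2 and
    mean = (k sum d_t / sigma2 + lam/tau^2) / precision.
    """
    cp = state.countries[c]
    h = state.hyper
    tau2 = h.tau * h.tau
    prev, curr = _transitions(data, c)
    if prev.size == 0:
        return NormalCond(h.lam, tau2)
    k = 1.0 - cp.phi
    d = curr - cp.phi * prev
    precision = prev.size * k * k / cp.sigma2 + 1.0 / tau2
    mean = (k * float(np.sum(d)) / cp.sigma2 + h.lam / tau2) / precision
    return NormalCond(mean, 1.0 / precision)


def cond_phi(c: int, state: ModelParams, data: MigrationDataset) -> TruncNormalCond:
    """Full conditional of phi_c: normal truncated to (0,1).

    With x_t = r_{t-1} - mu and z_t = r_t - mu, the untruncated moments are
    mean = sum(x z) / sum(x^2), var = sigma2 / sum(x^2).  A degenerate
    design (all x_t = 0, or no transitions) leaves the U(0,1) prior.
    """
    cp = state.countries[c]
    prev, curr = _transitions(data, c)
    if prev.size == 0:
        return TruncNormalCond(0.5, np.inf, 0.0, 1.0, flat=True)
    x = prev - cp.mu
    z = curr - cp.mu
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        return TruncNormalCond(0.5, np.inf, 0.0, 1.0, flat=True)
    mean = float(np.sum(x * z)) / sxx
    var = cp.sigma2 / sxx
    return TruncNormalCond(mean, var, 0.0, 1.0)


def cond_sigma2(c: int, state: ModelParams, data: MigrationDataset) -> InvGammaCond:
    """Full conditional of sigma2_c: IG(a + (T-1)/2, b + sum(eps^2)/2)."""
    cp = state.countries[c]
    h = state.hyper
    prev, curr = _transitions(data, c)
    if prev.size == 0:
        return InvGammaCond(h.a, h.b)
    eps = (curr - cp.mu) - cp.phi * (prev - cp.mu)
    return InvGammaCond(h.a + prev.size / 2.0, h.b + 0.5 * float(np.sum(eps * eps)))


def cond_b(state: ModelParams) -> TruncGammaCond:
    """Full conditional of b: Gamma(C a + 1, sum 1/sigma2_c) truncated above.

    p(b | .) is proportional to b^(C a) exp(-b sum 1/sigma2) on
    (0, 100(a-1)).
    """
    h = state.hyper
    C = state.n_countries
    rate = float(np.sum(1.0 / state.sigma2_vector())) if C else 0.0
    return TruncGammaCond(C * h.a + 1.0, rate, B_UPPER_FACTOR * (h.a - 1.0))


def cond_lambda(state: ModelParams) -> TruncNormalCond:
    """Full conditional of lam: N(mean mu_c, tau^2/C) truncated to (-100,100)."""
    h = state.hyper
    C = state.n_countries
    if C == 0:
        return TruncNormalCond(0.0, np.inf, *LAMBDA_BOUNDS, flat=True)
    mu = state.mu_vector()
    return TruncNormalCond(
        float(np.mean(mu)), h.tau * h.tau / C, LAMBDA_BOUNDS[0], LAMBDA_BOUNDS[1]
    )


def log_cond_tau(tau: float, state: ModelParams) -> float:
    """Log full-conditional kernel of tau on (0,100); -inf outside."""
    if not (TAU_BOUNDS[0] < tau < TAU_BOUNDS[1]):
        return -math.inf
    h = state.hyper
    mu = state.mu_vector()
    C = mu.size
    return -C * math.log(tau) - float(np.sum((mu - h.lam) ** 2)) / (2.0 * tau * tau)


def log_cond_a(a: float, state: ModelParams) -> float:
    """Log full-conditional kernel of a on (1,10), requiring b < 100(a-1).

    Collects every a-dependent term: the IG(a,b) normalizing constant and
    exponent across countries, and the b|a ~ U(0, 100(a-1)) prior density.
    """
    if not (A_BOUNDS[0] < a < A_BOUNDS[1]):
        return -math.inf
    h = state.hyper
    if h.b >= B_UPPER_FACTOR * (a - 1.0):
        return -math.inf
    sigma2 = state.sigma2_vector()
    C = sigma2.size
    out = C * (a * math.log(h.b) - math.lgamma(a))
    out += -(a + 1.0) * float(np.sum(np.log(sigma2)))
    out += -math.log(B_UPPER_FACTOR * (a - 1.0))
    return out
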