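"""Posterior sampling for the hierarchical AR(1) model.

One sweep updates, in fixed order: each mu_c (Gibbs), each phi_c (Gibbs
from a truncated normal), each sigma2_c (Gibbs), lam (Gibbs, truncated
normal), tau (slice), a (slice), b (Gibbs, truncated gamma).  Truncated
draws use inverse-CDF sampling on the closed forms, with quantiles clamped
away from 0/1 by 1e-12.  tau and a have bounded supports, so their slice
sampler shrinks from the full support interval — no step-size tuning and
fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special

from . import model as hm
from .data_io import MigrationDataset
from .model import CountryParams, HyperParams, ModelParams

__all__ = [
    "McmcConfig",
    "PosteriorSample",
    "run_mcmc",
    "diagnostics",
    "slice_sample_bounded",
    "sample_truncated_normal",
    "sample_truncated_gamma",
]

_QCLAMP = 1e-12


class DivergenceError(RuntimeError):
    """A sampler state became non-finite."""


@dataclass
class McmcConfig:
    n_iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 10
    n_chains: int = 3
    seed: int = 0
    slice_width: float = 1.0  # retained for API compatibility; bounded slices shrink from the full support
    init_strategy: str = "data"

    def validate(self) -> None:
        if not (self.n_iterations > self.burn_in >= 0):
            raise ValueError("need n_iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSample:
    """Stacked posterior draws across chains.

    Country-indexed arrays have shape (N, C); hyperparameter arrays (N,).
    """

    country_ids: list[str]
    mu: np.ndarray
    phi: np.ndarray
    sigma2: np.ndarray
    lam: np.ndarray
    tau: np.ndarray
    a: np.ndarray
    b: np.ndarray
    chain_ids: np.ndarray
    config: McmcConfig = None

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def n_countries(self) -> int:
        return self.mu.shape[1]

    def params_at(self, i: int) -> ModelParams:
        """Materialize draw ``i`` as a ModelParams."""
        countries = [
            CountryParams(self.mu[i, c], self.phi[i, c], self.sigma2[i, c])
            for c in range(self.n_countries)
        ]
        hyper = HyperParams(self.lam[i], self.tau[i], self.a[i], self.b[i])
        return ModelParams(countries=countries, hyper=hyper)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, draw, parameter, value."""
        rows = {"chain": [], "draw": [], "parameter": [], "value": []}

        def emit(name, values):
            rows["chain"].extend(self.chain_ids.tolist())
            rows["draw"].extend(range(self.n_draws))
            rows["parameter"].extend([name] * self.n_draws)
            rows["value"].extend(np.asarray(values).tolist())

        for c, cid in enumerate(self.country_ids):
            emit(f"mu[{cid}]", self.mu[:, c])
            emit(f"phi[{cid}]", self.phi[:, c])
            emit(f"sigma2[{cid}]", self.sigma2[:, c])
        emit("lambda", self.lam)
        emit("tau", self.tau)
        emit("a", self.a)
        emit("b", self.b)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["value"] = df["value"].map(repr)  # shortest round-trip formatting
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSample":
        df = pd.read_csv(path, float_precision="round_trip")
        wide = df.pivot(index=["chain", "draw"], columns="parameter", values="value")
        wide = wide.sort_index()
        cids = []
        for p in wide.columns:
            if p.startswith("mu[") and p.endswith("]"):
                cids.append(p[3:-1])
        chain_ids = wide.index.get_level_values("chain").to_numpy()
        def mat(prefix):
            return np.column_stack([wide[f"{prefix}[{cid}]"] for cid in cids])
        return cls(
            country_ids=cids,
            mu=mat("mu"),
            phi=mat("phi"),
            sigma2=mat("sigma2"),
            lam=wide["lambda"].to_numpy(),
            tau=wide["tau"].to_numpy(),
            a=wide["a"].to_numpy(),
            b=wide["b"].to_numpy(),
            chain_ids=chain_ids,
        )


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def sample_truncated_normal(rng, mean, sd, lower, upper):
    """Inverse-CDF draw from N(mean, sd^2) truncated to (lower, upper)."""
    lo = special.ndtr((lower - mean) / sd)
    hi = special.ndtr((upper - mean) / sd)
    u = lo + rng.random() * (hi - lo)
    u = min(max(u, _QCLAMP), 1.0 - _QCLAMP)
    return float(mean + sd * special.ndtri(u))


def sample_truncated_gamma(rng, shape, rate, upper):
    """Inverse-CDF draw from Gamma(shape, rate) truncated to (0, upper)."""
    hi = special.gammainc(shape, upper * rate)
    u = rng.random() * hi
    u = min(max(u, _QCLAMP), 1.0 - _QCLAMP)
    return float(special.gammaincinv(shape, u) / rate)


def slice_sample_bounded(logf, x0, lower, upper, rng, max_shrink=200):
    """One slice-sampling update on a bounded support.

    The initial bracket is the full support (no stepping out needed);
    rejected proposals shrink the bracket toward the current point.
    """
    ly = logf(x0)
    if not np.isfinite(ly):
        raise DivergenceError(f"slice sampler started outside support at {x0}")
    log_slice = ly - rng.exponential()
    lo, hi = lower, upper
    for _ in range(max_shrink):
        x1 = lo + rng.random() * (hi - lo)
        if logf(x1) > log_slice:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # bracket collapsed numerically; keep current point


# ---------------------------------------------------------------------------
# Main sampler
# ---------------------------------------------------------------------------

def _initial_state(data: MigrationDataset) -> ModelParams:
    """Data-informed starting point, always inside every support."""
    C = data.n_countries
    mu0 = np.empty(C)
    s20 = np.empty(C)
    for c in range(C):
        r = data.observed_rates(c)
        mu0[c] = float(np.mean(r))
        s20[c] = max(float(np.var(r)), 1e-4)
    lam0 = float(np.clip(np.mean(mu0), -99.0, 99.0))
    tau0 = float(np.clip(np.std(mu0), 0.01, 99.0))
    a0 = 2.0
    b_upper = hm.B_UPPER_FACTOR * (a0 - 1.0)
    b0 = float(np.clip((a0 - 1.0) * np.median(s20), 1e-6, b_upper - 1e-6))
    countries = [CountryParams(mu0[c], 0.5, s20[c]) for c in range(C)]
    return ModelParams(
        countries=countries, hyper=HyperParams(lam0, tau0, a0, b0)
    )


def _check_finite(state: ModelParams, iteration: int, chain: int) -> None:
    vals = {
        "mu": state.mu_vector(),
        "phi": state.phi_vector(),
        "sigma2": state.sigma2_vector(),
        "lambda": state.hyper.lam,
        "tau": state.hyper.tau,
        "a": state.hyper.a,
        "b": state.hyper.b,
    }
    for name, v in vals.items():
        if not np.all(np.isfinite(v)):
            raise DivergenceError(
                f"non-finite {name} at iteration {iteration} (chain {chain})"
            )


def _sweep(state: ModelParams, data: MigrationDataset, rng,
           update_hypers: bool = True,
           frozen: frozenset = frozenset()) -> ModelParams:
    """One full Gibbs/slice sweep, in the documented update order.

    ``frozen`` names parameter blocks ('mu', 'phi', 'sigma2', 'lambda',
    'tau', 'a', 'b') left untouched — used by validation tests.
    """
    C = state.n_countries
    if "mu" not in frozen:
        for c in range(C):
            cond = hm.cond_mu(c, state, data)
            state.countries[c].mu = rng.normal(cond.mean, math.sqrt(cond.var))
    if "phi" not in frozen:
        for c in range(C):
            cond = hm.cond_phi(c, state, data)
            if cond.flat:
                state.countries[c].phi = rng.random()
            else:
                state.countries[c].phi = sample_truncated_normal(
                    rng, cond.mean, math.sqrt(cond.var), cond.lower, cond.upper
                )
    if "sigma2" not in frozen:
        for c in range(C):
            cond = hm.cond_sigma2(c, state, data)
            # 1/Gamma(shape, rate) ~ IG(shape, rate)
            state.countries[c].sigma2 = cond.rate / rng.gamma(cond.shape)
    if update_hypers:
        if "lambda" not in frozen:
            cond = hm.cond_lambda(state)
            state.hyper.lam = sample_truncated_normal(
                rng, cond.mean, math.sqrt(cond.var), cond.lower, cond.upper
            )
        if "tau" not in frozen:
            state.hyper.tau = slice_sample_bounded(
                lambda t: hm.log_cond_tau(t, state),
                state.hyper.tau,
                *hm.TAU_BOUNDS,
                rng=rng,
            )
        if "a" not in frozen:
            state.hyper.a = slice_sample_bounded(
                lambda av: hm.log_cond_a(av, state),
                state.hyper.a,
                *hm.A_BOUNDS,
                rng=rng,
            )
        if "b" not in frozen:
            cond = hm.cond_b(state)
            state.hyper.b = sample_truncated_gamma(
                rng, cond.shape, cond.rate, cond.upper
            )
    return state


def run_mcmc(data: MigrationDataset, config: McmcConfig | None = None,
             frozen: frozenset = frozenset(),
             init: ModelParams | None = None) -> PosteriorSample:
    """Draw posterior samples of all parameters.

    Deterministic: identical (data, config) give bitwise-identical draws.
    ``frozen``/``init`` are hooks for validation experiments (freeze blocks
    at their initial values).
    """
    config = config or McmcConfig()
    config.validate()
    n_keep = config.n_chains * config.draws_per_chain
    C = data.n_countries
    out = {
        "mu": np.empty((n_keep, C)),
        "phi": np.empty((n_keep, C)),
        "sigma2": np.empty((n_keep, C)),
        "lam": np.empty(n_keep),
        "tau": np.empty(n_keep),
        "a": np.empty(n_keep),
        "b": np.empty(n_keep),
        "chain": np.empty(n_keep, dtype=int),
    }
    i_keep = 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        if init is not None:
            state = ModelParams(
                countries=[replace(cp) for cp in init.countries],
                hyper=replace(init.hyper),
            )
        else:
            state = _initial_state(data)
        for it in range(config.n_iterations):
            state = _sweep(state, data, rng, frozen=frozen)
            _check_finite(state, it, chain)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                out["mu"][i_keep] = state.mu_vector()
                out["phi"][i_keep] = state.phi_vector()
                out["sigma2"][i_keep] = state.sigma2_vector()
                out["lam"][i_keep] = state.hyper.lam
                out["tau"][i_keep] = state.hyper.tau
                out["a"][i_keep] = state.hyper.a
                out["b"][i_keep] = state.hyper.b
                out["chain"][i_keep] = chain
                i_keep += 1
    assert i_keep == n_keep
    return PosteriorSample(
        country_ids=list(data.country_ids),
        mu=out["mu"],
        phi=out["phi"],
        sigma2=out["sigma2"],
        lam=out["lam"],
        tau=out["tau"],
        a=out["a"],
        b=out["b"],
        chain_ids=out["chain"],
        config=config,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat on an (n_chains, n_draws) array."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    halves = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    k, h = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    bvar = h * means.var(ddof=1)
    if w == 0:
        return 1.0 if bvar == 0 else np.inf
    var_plus = (h - 1) / h * w + bvar / h
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk ESS via Geyer initial-positive-sequence autocorrelation sums."""
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acov = np.zeros((m, n))
    for j in range(m):
        x = chains[j] - chains[j].mean()
        full = np.correlate(x, x, mode="full")[n - 1:]
        acov[j] = full / n
    var_within = acov[:, 0].mean()
    if var_within == 0:
        return float(m * n)
    mean_var = chains.var(axis=1, ddof=1).mean()
    var_plus = mean_var * (n - 1) / n + chains.mean(axis=1).var(ddof=0)
    rho = 1.0 - (mean_var - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive
    tau_sum = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau_sum += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tau_sum)
    return float(max(ess, 1.0))


def diagnostics(sample: PosteriorSample) -> pd.DataFrame:
    """Per-parameter summary: mean, sd, quantiles, split-R-hat, ESS.

    A single chain is split into halves for R-hat.  Parameters with
    R-hat > 1.05 carry ``flagged=True``.
    """
    chains = np.unique(sample.chain_ids)
    rows = []

    def add(name, values):
        values = np.asarray(values)
        per_chain = np.stack([values[sample.chain_ids == ch] for ch in chains])
        q = np.quantile(values, [0.025, 0.5, 0.975])
        rhat = split_rhat(per_chain)
        rows.append(
            {
                "parameter": name,
                "mean": values.mean(),
                "sd": values.std(ddof=1) if values.size > 1 else 0.0,
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": rhat,
                "ess": effective_sample_size(per_chain),
                "flagged": bool(rhat > 1.05) if np.isfinite(rhat) else True,
            }
        )

    for c, cid in enumerate(sample.country_ids):
        add(f"mu[{cid}]", sample.mu[:, c])
        add(f"phi[{cid}]", sample.phi[:, c])
        add(f"sigma2[{cid}]", sample.sigma2[:, c])
    add("lambda", sample.lam)
    add("tau", sample.tau)
    add("a", sample.a)
    add("b", sample.b)
    return pd.DataFrame(rows)
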