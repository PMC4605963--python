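"""Synthetic WPP-like datasets with known ground truth.

Generates hierarchically drawn country parameters, AR(1) rate series
started from the stationary distribution, log-uniform populations with
constant per-country growth, and smooth young-adult-peaked migration
schedules.  Everything is deterministic given the seed, and the returned
truths support parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    AGE_GROUPS,
    SEXES,
    MigrationDataset,
    MigrationSchedule,
    PopulationProjection,
)
from .model import CountryParams, HyperParams, ModelParams

__all__ = ["SyntheticSpec", "SyntheticWorld", "generate", "perturb_for_holdout"]

#: Generator defaults: rate magnitudes of a few per-thousand.
DEFAULT_HYPER = HyperParams(lam=0.0, tau=3.0, a=3.0, b=20.0)


@dataclass
class SyntheticSpec:
    C: int
    T: int
    hyper: HyperParams = field(default_factory=lambda: HyperParams(0.0, 3.0, 3.0, 20.0))
    pop_range: tuple = (1e5, 1e8)
    seed: int = 0
    schedule_shape: str = "young_adult"
    first_period: int = 1950
    period_length: int = 5
    horizon_periods: int = 18

    def validate(self) -> None:
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        self.hyper.validate()
        lo, hi = self.pop_range
        if not (0 < lo <= hi):
            raise ValueError("pop_range must be positive and ordered")


@dataclass
class SyntheticWorld:
    dataset: MigrationDataset
    params: ModelParams
    schedules: list
    future_pops: PopulationProjection
    #: the injected AR(1) innovations, shape (C, T-1), for recursion checks
    noise: np.ndarray = None


def _young_adult_schedule(country_id: str) -> MigrationSchedule:
    """Smooth unimodal schedule peaking in the young-adult age groups."""
    mids = np.array([2.5 + 5 * i for i in range(len(AGE_GROUPS) - 1)] + [85.0])
    shape = np.exp(-0.5 * ((mids - 22.5) / 12.0) ** 2)
    shape /= shape.sum() * len(SEXES)
    weights = {}
    for i, a in enumerate(AGE_GROUPS):
        for s in SEXES:
            weights[(a, s)] = float(shape[i])
    total = sum(weights.values())
    weights[(AGE_GROUPS[0], SEXES[0])] += 1.0 - total
    return MigrationSchedule(country_id=country_id, weights=weights)


def generate(spec: SyntheticSpec, sigma2_override=None) -> SyntheticWorld:
    """Draw a full synthetic world from the hierarchical model.

    ``sigma2_override`` replaces the hierarchically drawn innovation
    variances (an array broadcastable to C); the override bypasses the
    IG support for noise-free limit tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = spec.hyper
    C, T = spec.C, spec.T

    phi = rng.uniform(0.0, 1.0, size=C)
    mu = rng.normal(h.lam, h.tau, size=C)
    sigma2 = 1.0 / rng.gamma(h.a, 1.0 / h.b, size=C)  # IG(a, b)
    if sigma2_override is not None:
        sigma2 = np.broadcast_to(
            np.asarray(sigma2_override, dtype=float), (C,)
        ).copy()

    rates = np.empty((C, T))
    stat_sd = np.sqrt(sigma2 / (1.0 - phi**2))
    rates[:, 0] = mu + stat_sd * rng.standard_normal(C)
    noise = np.sqrt(sigma2)[:, None] * rng.standard_normal((C, T - 1))
    for t in range(1, T):
        rates[:, t] = mu + phi * (rates[:, t - 1] - mu) + noise[:, t - 1]

    lo, hi = spec.pop_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=C))
    growth = rng.uniform(0.98, 1.08, size=C)  # per-period multiplier
    t_idx = np.arange(T + spec.horizon_periods)
    pops_all = base[:, None] * growth[:, None] ** t_idx[None, :]

    country_ids = [f"C{i:03d}" for i in range(C)]
    period_starts = spec.first_period + spec.period_length * np.arange(T)
    dataset = MigrationDataset(
        country_ids=country_ids,
        period_starts=period_starts,
        rates=rates,
        populations=pops_all[:, :T],
        period_length=spec.period_length,
    )
    future_starts = (
        period_starts[-1]
        + spec.period_length * (1 + np.arange(spec.horizon_periods))
    )
    future_pops = PopulationProjection(
        country_ids=country_ids,
        period_starts=future_starts,
        populations=pops_all[:, T:],
    )
    params = ModelParams(
        countries=[CountryParams(mu[c], phi[c], sigma2[c]) for c in range(C)],
        hyper=HyperParams(h.lam, h.tau, h.a, h.b),
    )
    if spec.schedule_shape == "uniform":
        from .data_io import uniform_schedule

        schedules = [uniform_schedule(cid) for cid in country_ids]
    else:
        schedules = [_young_adult_schedule(cid) for cid in country_ids]
    return SyntheticWorld(
        dataset=dataset,
        params=params,
        schedules=schedules,
        future_pops=future_pops,
        noise=noise,
    )


def perturb_for_holdout(dataset: MigrationDataset, m: int):
    """Split the last m periods off; concatenating the pieces restores the input."""
    if not (1 <= m <= dataset.n_periods - 2):
        raise ValueError(
            f"m must satisfy 1 <= m <= T-2 = {dataset.n_periods - 2}, got {m}"
        )
    train = dataset.truncated(dataset.n_periods - m)
    held = dataset.tail(m)
    return train, held
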