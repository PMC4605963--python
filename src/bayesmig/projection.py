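"""Joint posterior-predictive trajectory simulation with zero-sum correction.

For each posterior draw (held fixed over the horizon), rates are stepped
forward one period at a time:

1. AR(1) step on the rate scale for all countries;
2. conversion to per-period counts using projected populations;
3. disaggregation by age and sex with per-country schedules;
4. per-cell redistribution of the global overflow in proportion to
   projected populations, enforcing zero world net migration;
5. aggregation back to corrected counts and rates.

The corrected rate of each period is the lag fed into the next step.
Because schedule weights sum to one per country, the aggregate corrected
count equals ``y_c - share_c * sum_j y_j`` independent of the schedule, so
totals are stored and per-cell corrected counts are materialized on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    AGE_GROUPS,
    SEXES,
    DataValidationError,
    MigrationDataset,
    PopulationProjection,
    counts_to_rates,
    rates_to_counts,
    uniform_schedule,
)
from .mcmc import PosteriorSample

__all__ = [
    "ProjectionConfig",
    "TrajectorySet",
    "simulate_rate_step",
    "disaggregate_counts",
    "zero_sum_correct",
    "project",
    "summarize",
    "correction_sensitivity",
]

DEFAULT_QUANTILES = (0.025, 0.1, 0.5, 0.9, 0.975)


@dataclass
class ProjectionConfig:
    horizon_periods: int
    period_length: int = 5
    n_trajectories: int = 4_000
    seed: int = 0
    quantile_levels: tuple = DEFAULT_QUANTILES

    def validate(self) -> None:
        if self.horizon_periods < 1:
            raise ValueError("horizon_periods must be >= 1")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        levels = np.asarray(self.quantile_levels, dtype=float)
        if np.any(levels <= 0) or np.any(levels >= 1) or np.any(np.diff(levels) <= 0):
            raise ValueError("quantile_levels must be strictly increasing in (0,1)")


@dataclass
class TrajectorySet:
    """Simulated joint future paths of corrected rates and counts.

    ``rates``/``counts`` hold the corrected values with shape (K, C, H);
    ``rates_uncorrected`` is retained for sensitivity checks.  ``weights``
    is the dense (C, A, S) schedule array used for disaggregation.
    """

    country_ids: list[str]
    period_starts: np.ndarray
    rates: np.ndarray
    counts: np.ndarray
    rates_uncorrected: np.ndarray
    populations: np.ndarray  # (C, H)
    period_length: int = 5
    weights: np.ndarray | None = None  # (C, A, S)
    age_groups: list = field(default_factory=lambda: list(AGE_GROUPS))
    sexes: list = field(default_factory=lambda: list(SEXES))

    @property
    def n_trajectories(self) -> int:
        return self.rates.shape[0]

    def counts_uncorrected(self) -> np.ndarray:
        return rates_to_counts(
            self.rates_uncorrected, self.populations[None, :, :], self.period_length
        )

    def age_sex_counts(self, k: int, t: int, corrected: bool = True) -> np.ndarray:
        """Per-cell counts for trajectory ``k`` and horizon period ``t``.

        Returns an array of shape (C, A, S).  Corrected cells subtract the
        population-proportional share of the world cell total.
        """
        if self.weights is None:
            raise DataValidationError("trajectory set has no schedules attached")
        y_unc = self.counts_uncorrected()[k, :, t]
        cells = y_unc[:, None, None] * self.weights
        if not corrected:
            return cells
        pop = self.populations[:, t]
        share = pop / pop.sum()
        overflow = cells.sum(axis=0)  # (A, S)
        return cells - share[:, None, None] * overflow[None, :, :]


def simulate_rate_step(mu, phi, sigma2, prev_rates, rng) -> np.ndarray:
    """One AR(1) step for all countries: mu + phi*(prev - mu) + noise."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    prev = np.asarray(prev_rates, dtype=float)
    eps = rng.standard_normal(prev.shape) * np.sqrt(sigma2)
    return mu + phi * (prev - mu) + eps


def disaggregate_counts(counts, weights) -> np.ndarray:
    """Split per-country net counts over age x sex cells.

    ``weights`` has shape (C, A, S) with rows summing to 1; output
    ``counts[:, None, None] * weights`` sums back to the input exactly.
    """
    counts = np.asarray(counts, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != counts.shape[0]:
        raise DataValidationError("one schedule required per country")
    return counts[:, None, None] * weights


def zero_sum_correct(counts, populations) -> np.ndarray:
    """Redistribute the global overflow in proportion to populations.

    ``corrected_c = counts_c - pop_c / sum(pop) * sum(counts)`` along the
    last axis.  Output sums to zero; already-balanced input is unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    populations = np.asarray(populations, dtype=float)
    total_pop = populations.sum(axis=-1, keepdims=True)
    if np.any(total_pop <= 0) or np.any(populations <= 0):
        raise DataValidationError("populations must be strictly positive")
    share = populations / total_pop
    overflow = counts.sum(axis=-1, keepdims=True)
    return counts - share * overflow


def _schedule_weights(schedules, country_ids, age_groups, sexes) -> np.ndarray:
    by_id = {s.country_id: s for s in schedules or []}
    mats = []
    for cid in country_ids:
        sched = by_id.get(cid)
        if sched is None:
            sched = uniform_schedule(cid, age_groups, sexes)
        mats.append(sched.as_array(age_groups, sexes))
    return np.stack(mats)


def project(
    posterior: PosteriorSample,
    data: MigrationDataset,
    future_pops: PopulationProjection,
    schedules=None,
    config: ProjectionConfig | None = None,
) -> TrajectorySet:
    """Simulate corrected joint trajectories from the posterior.

    Each trajectory uses one posterior draw held fixed over the whole
    horizon; if more trajectories than draws are requested, draws are
    resampled with replacement (seeded).  Deterministic given the seed.
    """
    if config is None:
        raise ValueError("a ProjectionConfig is required")
    config.validate()
    if posterior.n_draws == 0:
        raise ValueError("posterior is empty")
    if list(future_pops.country_ids) != list(data.country_ids):
        raise DataValidationError(
            "future population country set must match the dataset"
        )
    H = config.horizon_periods
    if future_pops.populations.shape[1] < H:
        raise DataValidationError(
            f"future populations cover {future_pops.populations.shape[1]} periods, "
            f"horizon needs {H}"
        )
    expected_start = data.period_starts[-1] + data.period_length
    if future_pops.period_starts[0] != expected_start:
        raise DataValidationError(
            f"future populations must start at {expected_start}, "
            f"got {future_pops.period_starts[0]}"
        )

    K = config.n_trajectories
    C = data.n_countries
    N = posterior.n_draws
    rng = np.random.default_rng([config.seed, 2026])
    if K <= N:
        draw_idx = np.arange(K)
    else:
        draw_idx = rng.choice(N, size=K, replace=True)

    mu = posterior.mu[draw_idx]          # (K, C)
    phi = posterior.phi[draw_idx]
    sigma2 = posterior.sigma2[draw_idx]

    pops = future_pops.populations[:, :H]
    weights = _schedule_weights(schedules, data.country_ids, AGE_GROUPS, SEXES)

    rates_unc = np.empty((K, C, H))
    rates_cor = np.empty((K, C, H))
    counts_cor = np.empty((K, C, H))

    prev = np.broadcast_to(data.rates[:, -1], (K, C)).copy()
    for t in range(H):
        r_unc = simulate_rate_step(mu, phi, sigma2, prev, rng)
        pop_t = pops[:, t]
        y_unc = rates_to_counts(
            r_unc, np.broadcast_to(pop_t, (K, C)), config.period_length
        )
        # aggregate of the per-cell correction (weights sum to 1 per country)
        y_cor = zero_sum_correct(y_unc, np.broadcast_to(pop_t, (K, C)))
        r_cor = counts_to_rates(
            y_cor, np.broadcast_to(pop_t, (K, C)), config.period_length
        )
        rates_unc[:, :, t] = r_unc
        rates_cor[:, :, t] = r_cor
        counts_cor[:, :, t] = y_cor
        prev = r_cor

    period_starts = expected_start + data.period_length * np.arange(H)
    return TrajectorySet(
        country_ids=list(data.country_ids),
        period_starts=period_starts,
        rates=rates_cor,
        counts=counts_cor,
        rates_uncorrected=rates_unc,
        populations=pops.copy(),
        period_length=config.period_length,
        weights=weights,
    )


def summarize(trajectories: TrajectorySet, levels=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Pointwise quantiles of corrected rates per country and period."""
    levels = tuple(levels)
    q = np.quantile(trajectories.rates, levels, axis=0)  # (L, C, H)
    rows = []
    for c, cid in enumerate(trajectories.country_ids):
        for t, start in enumerate(trajectories.period_starts):
            row = {"country_id": cid, "period_start": int(start)}
            for li, lev in enumerate(levels):
                row[f"q{lev:g}"] = q[li, c, t]
            rows.append(row)
    return pd.DataFrame(rows)


def correction_sensitivity(trajectories: TrajectorySet) -> dict:
    """Distribution of |corrected - uncorrected| rate changes.

    Returns the raw (K, C, H) array plus summary quantiles and the
    fraction of cases below 0.2 per-thousand.
    """
    delta = np.abs(trajectories.rates - trajectories.rates_uncorrected)
    q = np.quantile(delta, [0.5, 0.9, 0.95, 0.99])
    return {
        "abs_change": delta,
        "median": float(q[0]),
        "q90": float(q[1]),
        "q95": float(q[2]),
        "q99": float(q[3]),
        "frac_below_0.2": float(np.mean(delta < 0.2)),
    }
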