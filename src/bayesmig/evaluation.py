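"""Out-of-sample holdout evaluation and global migration-trend statistics.

Holdout evaluation withholds the ``m`` most recent periods, refits the
chosen forecaster on the truncated data only, and scores point forecasts
(median) against the withheld truths on the rate scale.  Coverage uses
closed intervals.  Trend statistics are the unweighted and
population-weighted means of absolute net migration rates, and the
fraction of countries switching between net-sender and net-receiver
parity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import GravityExponents, gravity_forecast_dataset, persistence_forecast
from .data_io import DataValidationError, MigrationDataset, PopulationProjection
from .mcmc import McmcConfig, run_mcmc
from .projection import ProjectionConfig, TrajectorySet, project

__all__ = [
    "HoldoutSpec",
    "EvalReport",
    "holdout_evaluate",
    "u_stat",
    "w_stat",
    "parity_change_fraction",
    "trend_projection",
]

FORECASTERS = ("bayesian", "gravity", "persistence_rates", "persistence_counts")


@dataclass
class HoldoutSpec:
    """Withhold the m most recent periods; score at each withheld lead."""

    m: int

    def validate(self, n_periods: int) -> None:
        if not (1 <= self.m < n_periods):
            raise ValueError(f"m must satisfy 1 <= m < T={n_periods}, got {self.m}")
        if n_periods - self.m < 2:
            raise ValueError("training series needs at least 2 periods")


@dataclass
class EvalReport:
    """Per-lead MAE (rate units) and interval coverage (percent)."""

    forecaster: str
    table: pd.DataFrame  # columns: lead_years, mae, cov80, cov95, n_countries
    by_region: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "model", self.forecaster)
        df.to_csv(path, index=False)


def _holdout_pops(data: MigrationDataset, m: int) -> PopulationProjection:
    """Withheld-period populations repackaged as the 'projected' populations."""
    tail = data.tail(m)
    return PopulationProjection(
        country_ids=list(data.country_ids),
        period_starts=tail.period_starts,
        populations=tail.populations,
    )


def holdout_evaluate(
    data: MigrationDataset,
    spec: HoldoutSpec,
    forecaster,
    mcmc_config: McmcConfig | None = None,
    projection_config: ProjectionConfig | None = None,
    gravity_exponents: GravityExponents | None = None,
    schedules=None,
    region_map: dict | None = None,
) -> EvalReport:
    """Refit on the first T-m periods and score the withheld m periods.

    ``forecaster`` is one of ``bayesian | gravity | persistence_rates |
    persistence_counts`` or a callable ``(train, m, future_pops) ->
    (median, intervals)`` where ``median`` is a (C, m) rate array and
    ``intervals`` is ``{level: (lo, hi)}`` or None.  Interval coverage is
    reported only when intervals are available; endpoints count as
    covering.
    """
    spec.validate(data.n_periods)
    m = spec.m
    train = data.truncated(data.n_periods - m)
    truth = data.rates[:, -m:]
    future_pops = _holdout_pops(data, m)

    intervals = None
    name = forecaster if isinstance(forecaster, str) else getattr(
        forecaster, "__name__", "custom"
    )
    if callable(forecaster):
        median, intervals = forecaster(train, m, future_pops)
        median = np.asarray(median, dtype=float)
    elif forecaster == "persistence_rates":
        median = persistence_forecast(train, "rates", m)
    elif forecaster == "persistence_counts":
        median = persistence_forecast(train, "counts", m, future_pops)
    elif forecaster == "gravity":
        if gravity_exponents is None:
            raise DataValidationError("gravity forecaster requires exponents")
        median = gravity_forecast_dataset(train, gravity_exponents, future_pops, m)
    elif forecaster == "bayesian":
        mcmc_config = mcmc_config or McmcConfig()
        posterior = run_mcmc(train, mcmc_config)
        projection_config = projection_config or ProjectionConfig(
            horizon_periods=m,
            period_length=data.period_length,
            n_trajectories=min(2_000, posterior.n_draws),
            seed=mcmc_config.seed,
        )
        projection_config.horizon_periods = m
        traj = project(posterior, train, future_pops, schedules, projection_config)
        median = np.median(traj.rates, axis=0)
        intervals = {
            0.80: (
                np.quantile(traj.rates, 0.10, axis=0),
                np.quantile(traj.rates, 0.90, axis=0),
            ),
            0.95: (
                np.quantile(traj.rates, 0.025, axis=0),
                np.quantile(traj.rates, 0.975, axis=0),
            ),
        }
    else:
        raise ValueError(f"unknown forecaster {forecaster!r}")

    if median.shape != truth.shape:
        raise DataValidationError(
            f"forecast shape {median.shape} does not match truth {truth.shape}"
        )

    rows = []
    observed = np.isfinite(truth)
    for lead in range(m):
        mask = observed[:, lead]
        err = np.abs(median[mask, lead] - truth[mask, lead])
        row = {
            "lead_years": (lead + 1) * data.period_length,
            "mae": float(np.mean(err)),
            "cov80": np.nan,
            "cov95": np.nan,
            "n_countries": int(mask.sum()),
        }
        if intervals is not None:
            for level, key in ((0.80, "cov80"), (0.95, "cov95")):
                if level in intervals:
                    lo, hi = intervals[level]
                    inside = (truth[mask, lead] >= lo[mask, lead]) & (
                        truth[mask, lead] <= hi[mask, lead]
                    )
                    row[key] = float(100.0 * np.mean(inside))
        rows.append(row)
    table = pd.DataFrame(rows)

    by_region = None
    if region_map is not None:
        regions = np.array([region_map.get(cid, "other") for cid in data.country_ids])
        reg_rows = []
        for reg in np.unique(regions):
            sel = regions == reg
            for lead in range(m):
                mask = sel & observed[:, lead]
                if not mask.any():
                    continue
                reg_rows.append(
                    {
                        "region": reg,
                        "lead_years": (lead + 1) * data.period_length,
                        "mae": float(
                            np.mean(np.abs(median[mask, lead] - truth[mask, lead]))
                        ),
                        "n_countries": int(mask.sum()),
                    }
                )
        by_region = pd.DataFrame(reg_rows)
    return EvalReport(forecaster=name, table=table, by_region=by_region)


# ---------------------------------------------------------------------------
# Trend statistics
# ---------------------------------------------------------------------------

def u_stat(rates) -> float:
    """Unweighted mean absolute net migration rate across countries."""
    rates = np.asarray(rates, dtype=float)
    return float(np.mean(np.abs(rates)))


def w_stat(rates, populations) -> float:
    """Population-weighted mean absolute net migration rate."""
    rates = np.asarray(rates, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if rates.shape != populations.shape:
        raise DataValidationError("rates and populations must align")
    w = populations / populations.sum()
    return float(np.sum(np.abs(rates) * w))


def _sign(x) -> np.ndarray:
    return np.sign(np.asarray(x, dtype=float))


def parity_change_fraction(base_rates, target, mode: str = "mean") -> float:
    """Fraction of countries whose net-migration sign flipped.

    A zero rate carries no parity and never counts as a switch.  ``target``
    may be observed rates (1-D, length C) or a (K, C) array of trajectory
    rates at one period; for trajectories, ``mode='mean'`` averages the
    per-trajectory switch fraction (a posterior predictive probability)
    while ``mode='median'`` evaluates the sign of the median trajectory.
    """
    s0 = _sign(base_rates)
    target = np.asarray(target, dtype=float)
    if target.ndim == 1:
        s1 = _sign(target)
        return float(np.mean(s0 * s1 == -1))
    if mode == "mean":
        s1 = _sign(target)  # (K, C)
        switched = s0[None, :] * s1 == -1
        return float(np.mean(switched.mean(axis=1)))
    if mode == "median":
        s1 = _sign(np.median(target, axis=0))
        return float(np.mean(s0 * s1 == -1))
    raise ValueError(f"unknown mode {mode!r}")


def trend_projection(
    trajectories: TrajectorySet,
    populations=None,
    levels=(0.025, 0.1, 0.5, 0.9, 0.975),
) -> pd.DataFrame:
    """Per-period quantiles of u(t) and w(t) across trajectories."""
    pops = trajectories.populations if populations is None else np.asarray(populations)
    K, C, H = trajectories.rates.shape
    u = np.abs(trajectories.rates).mean(axis=1)  # (K, H)
    wts = pops / pops.sum(axis=0, keepdims=True)  # (C, H)
    w = np.einsum("kch,ch->kh", np.abs(trajectories.rates), wts)
    rows = []
    for t, start in enumerate(trajectories.period_starts):
        for stat_name, series in (("u", u[:, t]), ("w", w[:, t])):
            row = {"statistic": stat_name, "period_start": int(start)}
            for lev in levels:
                row[f"q{lev:g}"] = float(np.quantile(series, lev))
            rows.append(row)
    return pd.DataFrame(rows)
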