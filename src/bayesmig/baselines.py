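"""Point-forecast comparison models: persistence and a gravity model.

Persistence repeats the most recently observed rate (or count) forever.
The gravity model writes expected in-migration to a country as
``a * L(t)^alpha * M(t)^beta`` and out-migration as
``b * L(t)^gamma * M(t)^delta`` where L is the country's own population and
M the rest-of-world population; per-country constants (a, b) are fit to
historical net counts by nonnegative least squares.  The exponents are
required config inputs — there are no defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .data_io import (
    DataValidationError,
    MigrationDataset,
    PopulationProjection,
    counts_to_rates,
    rates_to_counts,
)

__all__ = [
    "GravityExponents",
    "GravityFit",
    "CollinearDesignWarning",
    "persistence_forecast",
    "fit_gravity",
    "gravity_forecast",
    "gravity_forecast_dataset",
]


class CollinearDesignWarning(UserWarning):
    """In- and out-flow regressor columns are collinear; constants not separately identifiable."""


@dataclass(frozen=True)
class GravityExponents:
    """Power-law exponents shared across countries (config inputs)."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "delta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"gravity exponent {name} must be finite")


@dataclass
class GravityFit:
    """Fitted per-country proportionality constants.

    ``a_grav``/``b_grav`` are the nonnegative least-squares minimizers;
    ``unconstrained`` records the raw least-squares solution for
    diagnostics.
    """

    a_grav: float
    b_grav: float
    rss: float
    unconstrained: tuple = (np.nan, np.nan)
    collinear: bool = False


def persistence_forecast(
    data: MigrationDataset,
    kind: str,
    horizon: int,
    future_pops: PopulationProjection | None = None,
) -> np.ndarray:
    """Rates implied by holding the last observed rate or count fixed.

    kind='rates': the last observed rate repeats.  kind='counts': the last
    observed per-period count repeats; the implied rate then drifts as the
    projected population changes (requires ``future_pops``).
    Returns an array of shape (C, horizon).
    """
    if kind not in ("rates", "counts"):
        raise ValueError(f"kind must be 'rates' or 'counts', got {kind!r}")
    C = data.n_countries
    if kind == "rates":
        last_rate = data.rates[:, -1]
        return np.tile(last_rate[:, None], (1, horizon))
    if future_pops is None:
        raise DataValidationError("persistence of counts requires future populations")
    if future_pops.populations.shape[1] < horizon:
        raise DataValidationError("future populations do not cover the horizon")
    last_count = data.counts[:, -1]
    pops = future_pops.populations[:, :horizon]
    return counts_to_rates(
        np.tile(last_count[:, None], (1, horizon)), pops, data.period_length
    )


def fit_gravity(
    counts: np.ndarray,
    own_pop: np.ndarray,
    rest_pop: np.ndarray,
    exponents: GravityExponents,
) -> GravityFit:
    """Fit (a, b) >= 0 minimizing sum_t (y_t - [a u_t - b v_t])^2.

    u_t = L^alpha M^beta and v_t = L^gamma M^delta.  The objective is
    linear in (a, b), solved by nonnegative least squares; the exact
    unconstrained solution is returned when already nonnegative.  A
    rank-deficient design raises :class:`CollinearDesignWarning` and falls
    back to the minimum-norm solution (projected to the nonnegative
    minimizer when that solution leaves the support).
    """
    y = np.asarray(counts, dtype=float)
    L = np.asarray(own_pop, dtype=float)
    M = np.asarray(rest_pop, dtype=float)
    if y.size < 2:
        raise DataValidationError("gravity fit needs >= 2 historical periods")
    if np.any(L <= 0) or np.any(M <= 0):
        raise DataValidationError("populations must be positive for gravity fit")
    u = L ** exponents.alpha * M ** exponents.beta
    v = L ** exponents.gamma * M ** exponents.delta
    A = np.column_stack([u, -v])

    collinear = np.linalg.matrix_rank(A, tol=1e-10 * max(np.abs(A).max(), 1.0)) < 2
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    unconstrained = (float(sol[0]), float(sol[1]))
    if collinear:
        warnings.warn(
            "gravity design is collinear; only a-b is identifiable",
            CollinearDesignWarning,
            stacklevel=2,
        )
    if not collinear and sol[0] >= 0 and sol[1] >= 0:
        a_hat, b_hat = unconstrained
    else:
        x, _ = nnls(A, y)
        a_hat, b_hat = float(x[0]), float(x[1])
        if collinear and unconstrained[0] >= 0 and unconstrained[1] >= 0:
            a_hat, b_hat = unconstrained  # min-norm already admissible
    resid = y - (a_hat * u - b_hat * v)
    return GravityFit(
        a_grav=a_hat,
        b_grav=b_hat,
        rss=float(np.sum(resid**2)),
        unconstrained=unconstrained,
        collinear=collinear,
    )


def gravity_forecast(
    fit: GravityFit,
    exponents: GravityExponents,
    own_pop: np.ndarray,
    rest_pop: np.ndarray,
) -> np.ndarray:
    """Projected net counts a L^alpha M^beta - b L^gamma M^delta."""
    L = np.asarray(own_pop, dtype=float)
    M = np.asarray(rest_pop, dtype=float)
    return (
        fit.a_grav * L ** exponents.alpha * M ** exponents.beta
        - fit.b_grav * L ** exponents.gamma * M ** exponents.delta
    )


def gravity_forecast_dataset(
    data: MigrationDataset,
    exponents: GravityExponents,
    future_pops: PopulationProjection,
    horizon: int,
    as_rates: bool = True,
) -> np.ndarray:
    """Fit and forecast all countries; returns (C, horizon) rates or counts.

    L(t) is each country's own population and M(t) the world total minus
    L(t), both taken from the same population tables.
    """
    if future_pops.populations.shape[1] < horizon:
        raise DataValidationError("future populations do not cover the horizon")
    world_hist = np.nansum(data.populations, axis=0)
    pops_f = future_pops.populations[:, :horizon]
    world_fut = pops_f.sum(axis=0)
    out = np.empty((data.n_countries, horizon))
    first = data.first_observed()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CollinearDesignWarning)
        for c in range(data.n_countries):
            t0 = first[c]
            y = data.counts[c, t0:]
            L = data.populations[c, t0:]
            M = world_hist[t0:] - L
            fit = fit_gravity(y, L, M, exponents)
            out[c] = gravity_forecast(fit, exponents, pops_f[c], world_fut - pops_f[c])
    if as_rates:
        out = counts_to_rates(out, pops_f, data.period_length)
    return out
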