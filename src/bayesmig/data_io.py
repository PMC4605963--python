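"""Dataset containers and CSV I/O for net-migration data.

Conventions
-----------
Rates are ANNUAL net migrants per thousand population.  Counts are net
migrants over a whole period.  With a period length of ``p`` years the two
are linked elementwise by::

    count = rate / 1000 * population * p

Populations are period-average person counts supplied by the input; this
module never interpolates them.  Periods are labelled by their start year
and must lie on a regular grid (default spacing 5 years).  A country may
enter the sample late (leading missing periods) but interior gaps are
rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "DataValidationError",
    "StructuralError",
    "MigrationDataset",
    "MigrationSchedule",
    "PopulationProjection",
    "rates_to_counts",
    "counts_to_rates",
    "read_dataset",
    "write_dataset",
    "read_schedules",
    "write_schedules",
    "uniform_schedule",
    "read_population_projection",
    "write_population_projection",
    "write_trajectories",
    "write_quantiles",
]

#: Default five-year age grid (17 groups) used when disaggregating counts.
AGE_GROUPS = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80+",
]

SEXES = ["F", "M"]


class DataValidationError(ValueError):
    """Raised when input values violate a dataset invariant."""


class StructuralError(ValueError):
    """Raised when an input file is malformed (duplicates, bad columns)."""


def rates_to_counts(rates, populations, period_length=5):
    """Convert annual per-thousand rates to per-period net counts.

    ``count = rate / 1000 * population * period_length`` elementwise.
    Exact inverse of :func:`counts_to_rates`.
    """
    rates = np.asarray(rates, dtype=float)
    populations = np.asarray(populations, dtype=float)
    try:
        np.broadcast_shapes(rates.shape, populations.shape)
    except ValueError:
        raise DataValidationError(
            f"shape mismatch: rates {rates.shape} vs populations {populations.shape}"
        ) from None
    return rates / 1000.0 * populations * period_length


def counts_to_rates(counts, populations, period_length=5):
    """Convert per-period net counts to annual per-thousand rates."""
    counts = np.asarray(counts, dtype=float)
    populations = np.asarray(populations, dtype=float)
    try:
        np.broadcast_shapes(counts.shape, populations.shape)
    except ValueError:
        raise DataValidationError(
            f"shape mismatch: counts {counts.shape} vs populations {populations.shape}"
        ) from None
    return counts * 1000.0 / (populations * period_length)


@dataclass
class MigrationDataset:
    """Per-country time series of net migration rates, counts and populations.

    Attributes
    ----------
    country_ids : list of str
        Ordered country codes; the row order of all matrices.
    period_starts : ndarray of int
        Ordered period start years on a regular grid.
    rates : ndarray, shape (C, T)
        Annual net migrants per thousand.  NaN allowed only as a leading
        prefix per country (late-entering country).
    populations : ndarray, shape (C, T)
        Period-average persons; strictly positive where rates are observed.
    counts : ndarray, shape (C, T)
        Net migrants per period; derived from rates if not supplied.
    period_length : int
        Years per period (default 5).
    """

    country_ids: list[str]
    period_starts: np.ndarray
    rates: np.ndarray
    populations: np.ndarray
    counts: np.ndarray | None = None
    period_length: int = 5

    def __post_init__(self):
        self.period_starts = np.asarray(self.period_starts, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.counts is None:
            self.counts = rates_to_counts(
                self.rates, self.populations, self.period_length
            )
        else:
            self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    # -- basic shape helpers -------------------------------------------------

    @property
    def n_countries(self) -> int:
        return len(self.country_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_starts)

    def first_observed(self) -> np.ndarray:
        """Index of the first non-missing period per country."""
        obs = np.isfinite(self.rates)
        out = np.full(self.n_countries, self.n_periods, dtype=int)
        any_obs = obs.any(axis=1)
        out[any_obs] = obs[any_obs].argmax(axis=1)
        return out

    def observed_rates(self, c: int) -> np.ndarray:
        """The contiguous observed rate series for country index ``c``."""
        return self.rates[c, self.first_observed()[c]:]

    def validate(self) -> None:
        C, T = self.rates.shape
        if len(self.country_ids) != C:
            raise DataValidationError("country_ids length does not match rates rows")
        if len(self.period_starts) != T:
            raise DataValidationError("period_starts length does not match rates cols")
        if len(set(self.country_ids)) != C:
            raise StructuralError("duplicate country_ids")
        if T >= 2:
            diffs = np.diff(self.period_starts)
            if np.any(diffs <= 0):
                raise DataValidationError("period_starts must be strictly increasing")
            if np.any(diffs != self.period_length):
                raise DataValidationError(
                    "period grid spacing must equal period_length "
                    f"({self.period_length}); got spacings {sorted(set(diffs))}"
                )
        if self.populations.shape != (C, T):
            raise DataValidationError("populations shape mismatch")
        if self.counts.shape != (C, T):
            raise DataValidationError("counts shape mismatch")

        obs = np.isfinite(self.rates)
        for c in range(C):
            row = obs[c]
            if not row.any():
                raise DataValidationError(
                    f"country {self.country_ids[c]} has no observed periods"
                )
            first = row.argmax()
            if not row[first:].all():
                raise DataValidationError(
                    f"country {self.country_ids[c]} has an interior gap in its "
                    "rate series; only leading missing periods are allowed"
                )
        pop_obs = self.populations[obs]
        if not np.all(np.isfinite(pop_obs)) or np.any(pop_obs <= 0):
            bad_c, bad_t = np.argwhere(
                obs & ~(np.isfinite(self.populations) & (self.populations > 0))
            )[0]
            raise DataValidationError(
                f"non-positive or missing population for country "
                f"{self.country_ids[bad_c]} period {self.period_starts[bad_t]}"
            )
        expected = rates_to_counts(self.rates, self.populations, self.period_length)
        got = self.counts[obs]
        want = expected[obs]
        scale = np.maximum(np.abs(want), 1.0)
        if np.any(np.abs(got - want) > 1e-9 * scale):
            raise DataValidationError(
                "counts inconsistent with rates x population x period_length / 1000"
            )

    # -- transformations -----------------------------------------------------

    def truncated(self, n_periods: int) -> "MigrationDataset":
        """A copy keeping only the first ``n_periods`` periods."""
        return MigrationDataset(
            country_ids=list(self.country_ids),
            period_starts=self.period_starts[:n_periods].copy(),
            rates=self.rates[:, :n_periods].copy(),
            populations=self.populations[:, :n_periods].copy(),
            counts=self.counts[:, :n_periods].copy(),
            period_length=self.period_length,
        )

    def tail(self, m: int) -> "MigrationDataset":
        """A copy keeping only the last ``m`` periods."""
        return MigrationDataset(
            country_ids=list(self.country_ids),
            period_starts=self.period_starts[-m:].copy(),
            rates=self.rates[:, -m:].copy(),
            populations=self.populations[:, -m:].copy(),
            counts=self.counts[:, -m:].copy(),
            period_length=self.period_length,
        )


@dataclass
class MigrationSchedule:
    """Age x sex weights distributing a country's net count over cells.

    Weights sum to 1 per country; negative entries are permitted because
    net migration schedules can change sign by age.
    """

    country_id: str
    weights: dict = field(default_factory=dict)  # {(age_group, sex): float}

    def __post_init__(self):
        total = sum(self.weights.values())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"schedule weights for {self.country_id} sum to {total!r}, not 1"
            )

    def as_array(self, age_groups=None, sexes=None) -> np.ndarray:
        """Dense (A, S) weight matrix on the given grid (zeros where absent)."""
        age_groups = age_groups if age_groups is not None else AGE_GROUPS
        sexes = sexes if sexes is not None else SEXES
        out = np.zeros((len(age_groups), len(sexes)))
        for (a, s), wgt in self.weights.items():
            out[age_groups.index(a), sexes.index(s)] = wgt
        return out


def uniform_schedule(country_id: str, age_groups=None, sexes=None) -> MigrationSchedule:
    """Default schedule: uniform over the full age x sex grid."""
    age_groups = age_groups if age_groups is not None else AGE_GROUPS
    sexes = sexes if sexes is not None else SEXES
    n = len(age_groups) * len(sexes)
    weights = {(a, s): 1.0 / n for a in age_groups for s in sexes}
    # exact sum-to-1 despite rounding
    first = (age_groups[0], sexes[0])
    weights[first] += 1.0 - sum(weights.values())
    return MigrationSchedule(country_id=country_id, weights=weights)


@dataclass
class PopulationProjection:
    """Exogenous projected period-average populations for future periods."""

    country_ids: list[str]
    period_starts: np.ndarray
    populations: np.ndarray  # (C, H)

    def __post_init__(self):
        self.period_starts = np.asarray(self.period_starts, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        C, H = self.populations.shape
        if len(self.country_ids) != C or len(self.period_starts) != H:
            raise DataValidationError("population projection shape mismatch")
        if np.any(~np.isfinite(self.populations)) or np.any(self.populations <= 0):
            raise DataValidationError("projected populations must be positive")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _to_csv_exact(df: pd.DataFrame, path) -> None:
    """Write CSV with shortest-round-trip float formatting (bit-exact reload)."""
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


def read_dataset(path, kind: str = "rates", period_length: int = 5) -> MigrationDataset:
    """Read a WPP-style long CSV into a :class:`MigrationDataset`.

    Expected columns: ``country_id, period_start, value, population`` with
    one row per (country, period).  ``kind`` declares whether ``value``
    holds rates or counts; the other is derived.
    """
    if kind not in ("rates", "counts"):
        raise ValueError(f"kind must be 'rates' or 'counts', got {kind!r}")
    df = pd.read_csv(path, dtype={"country_id": str}, float_precision="round_trip")
    required = {"country_id", "period_start", "value", "population"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralError(f"missing columns in {path}: {sorted(missing)}")
    dup = df.duplicated(subset=["country_id", "period_start"])
    if dup.any():
        row = df[dup].iloc[0]
        raise StructuralError(
            f"duplicate (country, period) row: ({row.country_id}, {row.period_start})"
        )
    bad_pop = ~(np.isfinite(df["population"]) & (df["population"] > 0))
    if bad_pop.any():
        row = df[bad_pop].iloc[0]
        raise DataValidationError(
            f"non-positive population for country {row.country_id} "
            f"period {row.period_start}"
        )
    periods = np.sort(df["period_start"].unique())
    if len(periods) >= 2:
        spac = np.diff(periods)
        if np.any(spac != period_length):
            # name one offending country for the error message
            counts = df.groupby("country_id")["period_start"].apply(
                lambda s: np.sort(s.to_numpy())
            )
            offender = df["country_id"].iloc[0]
            for cid, ps in counts.items():
                if len(ps) >= 2 and np.any(np.diff(ps) != period_length):
                    offender = cid
                    break
            raise DataValidationError(
                f"ragged period grid (country {offender}): periods {periods.tolist()} "
                f"not on a {period_length}-year grid"
            )
    country_ids = list(pd.unique(df["country_id"]))
    value = df.pivot(index="country_id", columns="period_start", values="value")
    pop = df.pivot(index="country_id", columns="period_start", values="population")
    value = value.reindex(index=country_ids, columns=periods)
    pop = pop.reindex(index=country_ids, columns=periods)
    vmat = value.to_numpy(dtype=float)
    pmat = pop.to_numpy(dtype=float)
    if kind == "rates":
        rates = vmat
        counts = None
    else:
        with np.errstate(invalid="ignore"):
            rates = counts_to_rates(vmat, pmat, period_length)
        counts = vmat
    return MigrationDataset(
        country_ids=country_ids,
        period_starts=periods,
        rates=rates,
        populations=pmat,
        counts=counts,
        period_length=period_length,
    )


def write_dataset(dataset: MigrationDataset, path, kind: str = "rates") -> None:
    """Write a dataset back to the long CSV dialect read by :func:`read_dataset`."""
    if kind not in ("rates", "counts"):
        raise ValueError(f"kind must be 'rates' or 'counts', got {kind!r}")
    mat = dataset.rates if kind == "rates" else dataset.counts
    rows = []
    for c, cid in enumerate(dataset.country_ids):
        for t, start in enumerate(dataset.period_starts):
            if not np.isfinite(dataset.rates[c, t]):
                continue
            rows.append(
                {
                    "country_id": cid,
                    "period_start": int(start),
                    "value": mat[c, t],
                    "population": dataset.populations[c, t],
                }
            )
    _to_csv_exact(pd.DataFrame(rows), path)


def read_schedules(path, country_ids=None, attach_default: bool = False):
    """Read per-country age x sex schedules from CSV.

    Columns: ``country_id, age_group, sex, weight``.  Per-country weights
    must sum to 1 within 1e-6 (then renormalized exactly).  With
    ``attach_default`` true, countries from ``country_ids`` absent from the
    file get the uniform default schedule.
    """
    df = pd.read_csv(
        path,
        dtype={"country_id": str, "age_group": str, "sex": str},
        float_precision="round_trip",
    )
    required = {"country_id", "age_group", "sex", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralError(f"missing columns in {path}: {sorted(missing)}")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise DataValidationError(
            f"unknown sex label {df[bad_sex]['sex'].iloc[0]!r}; expected one of {SEXES}"
        )
    schedules = []
    for cid, grp in df.groupby("country_id", sort=False):
        total = grp["weight"].sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
            raise DataValidationError(
                f"schedule weights for {cid} sum to {total}, expected 1 within 1e-6"
            )
        weights = {
            (row.age_group, row.sex): row.weight / total
            for row in grp.itertuples(index=False)
        }
        schedules.append(MigrationSchedule(country_id=cid, weights=weights))
    if attach_default and country_ids is not None:
        have = {s.country_id for s in schedules}
        for cid in country_ids:
            if cid not in have:
                schedules.append(uniform_schedule(cid))
    return schedules


def write_schedules(schedules, path) -> None:
    rows = [
        {"country_id": s.country_id, "age_group": a, "sex": x, "weight": w}
        for s in schedules
        for (a, x), w in s.weights.items()
    ]
    _to_csv_exact(pd.DataFrame(rows), path)


def read_population_projection(path) -> PopulationProjection:
    """Read projected populations (columns country_id, period_start, population)."""
    df = pd.read_csv(path, dtype={"country_id": str}, float_precision="round_trip")
    required = {"country_id", "period_start", "population"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralError(f"missing columns in {path}: {sorted(missing)}")
    if df.duplicated(subset=["country_id", "period_start"]).any():
        raise StructuralError("duplicate (country, period) rows in population file")
    periods = np.sort(df["period_start"].unique())
    country_ids = list(pd.unique(df["country_id"]))
    pop = (
        df.pivot(index="country_id", columns="period_start", values="population")
        .reindex(index=country_ids, columns=periods)
        .to_numpy(dtype=float)
    )
    return PopulationProjection(
        country_ids=country_ids, period_starts=periods, populations=pop
    )


def write_population_projection(proj: PopulationProjection, path) -> None:
    rows = [
        {
            "country_id": cid,
            "period_start": int(start),
            "population": proj.populations[c, t],
        }
        for c, cid in enumerate(proj.country_ids)
        for t, start in enumerate(proj.period_starts)
    ]
    _to_csv_exact(pd.DataFrame(rows), path)


def write_trajectories(trajectories, path) -> None:
    """Write a TrajectorySet as long CSV.

    Columns: country_id, period_start, trajectory_index, rate, count
    (corrected values).
    """
    K, C, H = trajectories.rates.shape
    cid = np.repeat(trajectories.country_ids, H)
    start = np.tile(trajectories.period_starts, C)
    frames = []
    for k in range(K):
        frames.append(
            pd.DataFrame(
                {
                    "country_id": cid,
                    "period_start": start,
                    "trajectory_index": k,
                    "rate": trajectories.rates[k].ravel(),
                    "count": trajectories.counts[k].ravel(),
                }
            )
        )
    _to_csv_exact(pd.concat(frames, ignore_index=True), path)


def write_quantiles(summary: pd.DataFrame, path) -> None:
    """Write a quantile summary table (country_id, period_start, q* columns)."""
    _to_csv_exact(summary, path)
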