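"""Synthetic registry records and projection trajectories with known truth.

The real supercentenarian registry is registration-gated, and projection
trajectory exports depend on external software, so every pipeline stage is
exercised against synthetic stand-ins generated here.

Records: per country, age-110 attainments follow a homogeneous Poisson
process at a configured intensity over ``[b - lead, e]`` (the window plus a
lead-in during which earlier attainers can still die inside the window);
excess lifetimes are Exponential(λ_true); a record is *retained* only if
the death falls inside ``[b, e]`` — exactly the observability rule the
truncated likelihood models, producing both C1 and C2 records.  A
stationary attainment process keeps the inclusion probability analytic
(the registry's real attainment schedule is non-stationary; a
linear-growth intensity option is available for realism).

Trajectories: geometric growth of the 110-114 band count with
multiplicative log-normal noise, part shared across a trajectory (so each
path is coherently high or low) and part per-period, emulating the fan of
a probabilistic projection.
"""

from __future__ import annotations

import importlib.resources
import io
import math
from dataclasses import dataclass, field

import numpy as np

from .records import Dataset, DataError, DeathRecord, ObservationWindow, read_records
from .projections import GRID_YEARS, Trajectory, TrajectorySet, read_trajectories

__all__ = [
    "CountryCohort",
    "CohortConfig",
    "TrajectoryConfig",
    "GroundTruth",
    "default_cohort_config",
    "simulate_dataset",
    "simulate_trajectories",
    "fixture_small",
    "inclusion_probability",
]


@dataclass(frozen=True)
class CountryCohort:
    """One country's observation window and attainment process.

    ``intensity`` is the expected number of age-110 attainments per year
    over ``[start - lead, end]``; ``growth`` (per year, additive fraction
    of the base intensity) makes the process linearly non-stationary.
    """

    country: str
    start: float
    end: float
    intensity: float
    lead: float = 20.0
    growth: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"{self.country!r}: window start must precede end")
        if math.isinf(self.end):
            raise DataError(
                f"{self.country!r}: simulation needs a bounded window end"
            )
        if self.intensity < 0 or self.lead < 0:
            raise DataError(f"{self.country!r}: intensity and lead must be nonnegative")

    @property
    def span(self) -> float:
        return self.end - self.start + self.lead


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic registry draw."""

    cohorts: tuple[CountryCohort, ...]
    rate: float
    female_share: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise DataError("true rate must be positive")
        if not 0.0 <= self.female_share <= 1.0:
            raise DataError("female share must lie in [0, 1]")
        if not self.cohorts:
            raise DataError("at least one country cohort is required")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did: attainers drawn vs records retained."""

    rate: float
    n_attainers: int
    n_retained: int


# Thirteen countries with windows of 10-35 years and intensities shaped so
# the country shares resemble a real registry (one dominant country, a
# handful of mid-sized ones, a long tail), without claiming to replicate it.
_DEFAULT_COHORTS = (
    CountryCohort("US", 1980.0, 2015.0, 38.0),
    CountryCohort("FR", 1987.0, 2017.0, 21.0),
    CountryCohort("EW", 1968.0, 2017.0, 8.5),
    CountryCohort("JP", 1996.0, 2018.0, 9.0),
    CountryCohort("ES", 1988.0, 2016.0, 5.5),
    CountryCohort("DE", 1994.0, 2017.0, 3.5),
    CountryCohort("CA", 1985.0, 2010.0, 2.5),
    CountryCohort("BE", 1992.0, 2017.0, 1.8),
    CountryCohort("DK", 1996.0, 2014.0, 1.2),
    CountryCohort("AT", 2005.0, 2017.0, 1.0),
    CountryCohort("SE", 1986.0, 2003.0, 1.0),
    CountryCohort("NO", 1989.0, 2004.0, 0.8),
    CountryCohort("FI", 1996.0, 2015.0, 0.6),
)


def default_cohort_config(rate: float = 0.733, seed: int = 0) -> CohortConfig:
    """Registry-shaped default: 13 countries, 92% female share."""
    return CohortConfig(cohorts=_DEFAULT_COHORTS, rate=rate, female_share=0.92, seed=seed)


def inclusion_probability(cohort: CountryCohort, rate: float, n_grid: int = 2001) -> float:
    """P(death lands in the window) for an attainment time uniform on
    ``[start - lead, end]``, by quadrature over the attainment interval.

    For t < b the death must fall in [b - t, e - t] beyond age 110
    (probability e^{-λ(b-t)} - e^{-λ(e-t)}); for t in [b, e] it must come
    before e (probability 1 - e^{-λ(e-t)}).
    """
    t = np.linspace(cohort.start - cohort.lead, cohort.end, n_grid)
    lo = np.maximum(cohort.start - t, 0.0)
    p = np.exp(-rate * lo) - np.exp(-rate * (cohort.end - t))
    return float(np.trapezoid(p, t) / cohort.span)


def _draw_batch(
    config: CohortConfig,
    cohort_idx: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attainment times, excess lifetimes and retention flags for a batch of
    attainers with given country assignments."""
    starts = np.array([c.start for c in config.cohorts])[cohort_idx]
    ends = np.array([c.end for c in config.cohorts])[cohort_idx]
    leads = np.array([c.lead for c in config.cohorts])[cohort_idx]
    growth = np.array([c.growth for c in config.cohorts])[cohort_idx]

    u = rng.uniform(size=len(cohort_idx))
    span = ends - (starts - leads)
    # inverse-CDF for intensity ∝ 1 + growth·(t - t0): linear ramp or uniform
    ramp = growth * span
    with np.errstate(invalid="ignore"):
        frac = np.where(
            ramp > 0,
            (np.sqrt(1.0 + u * ramp * (ramp + 2.0)) - 1.0) / np.where(ramp > 0, ramp, 1.0),
            u,
        )
    t = (starts - leads) + frac * span
    x = rng.exponential(scale=1.0 / config.rate, size=len(cohort_idx))
    death = t + x
    retained = (death >= starts) & (death <= ends)
    return t, x, retained


def _make_records(
    config: CohortConfig,
    cohort_idx: np.ndarray,
    t: np.ndarray,
    x: np.ndarray,
    rng: np.random.Generator,
    start_id: int,
) -> list[DeathRecord]:
    sexes = np.where(rng.uniform(size=len(t)) < config.female_share, "F", "M")
    countries = [config.cohorts[i].country for i in cohort_idx]
    return [
        DeathRecord(
            record_id=f"syn{start_id + k:06d}",
            country=countries[k],
            sex=str(sexes[k]),
            attainment_time=float(t[k]),
            death_time=float(t[k] + x[k]),
            excess_age=float(x[k]),
        )
        for k in range(len(t))
    ]


def simulate_dataset(
    config: CohortConfig, target_retained: int | None = None
) -> tuple[Dataset, GroundTruth]:
    """Draw a synthetic registry.

    With ``target_retained`` unset, each country contributes a Poisson
    number of attainers (intensity x attainment span) and the retained
    count is random.  With it set, attainers are drawn country-by-weight
    until exactly that many retained records exist (attainment times are
    iid uniform given the homogeneous process, so the retained records
    remain an iid sample from the truncated law).
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([c.intensity * c.span for c in config.cohorts])
    if not weights.sum() > 0:
        raise DataError("all cohort intensities are zero")
    windows = {
        c.country: ObservationWindow(country=c.country, start=c.start, end=c.end)
        for c in config.cohorts
    }

    records: list[DeathRecord] = []
    n_attainers = 0
    if target_retained is None:
        counts = rng.poisson(weights)
        cohort_idx = np.repeat(np.arange(len(config.cohorts)), counts)
        n_attainers = len(cohort_idx)
        t, x, keep = _draw_batch(config, cohort_idx, rng)
        records = _make_records(
            config, cohort_idx[keep], t[keep], x[keep], rng, start_id=0
        )
        if not records:
            import warnings

            warnings.warn("configuration yielded zero retained records", RuntimeWarning)
    else:
        probs = weights / weights.sum()
        batch = max(256, int(target_retained * 2))
        while len(records) < target_retained:
            cohort_idx = rng.choice(len(config.cohorts), size=batch, p=probs)
            n_attainers += batch
            t, x, keep = _draw_batch(config, cohort_idx, rng)
            new = _make_records(
                config, cohort_idx[keep], t[keep], x[keep], rng, start_id=len(records)
            )
            records.extend(new)
        records = records[:target_retained]

    dataset = Dataset(records, windows)
    return dataset, GroundTruth(
        rate=config.rate, n_attainers=n_attainers, n_retained=dataset.n
    )


@dataclass(frozen=True)
class TrajectoryConfig:
    """Synthetic projection fan for the 110-114 band.

    ``base`` is the 2025 band count, ``growth`` the per-5-year multiplier,
    ``dispersion`` the log-scale sd of the multiplicative noise (a share
    ``shared_frac`` of its variance is a trajectory-level factor, the rest
    per-period).
    """

    base: float = 280.0
    growth: float = 1.5
    dispersion: float = 0.35
    n_trajectories: int = 1000
    shared_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base <= 0 or self.growth <= 0:
            raise DataError("base count and growth factor must be positive")
        if self.dispersion < 0 or not 0.0 <= self.shared_frac <= 1.0:
            raise DataError("dispersion must be >= 0 and shared_frac in [0, 1]")
        if self.n_trajectories < 1:
            raise DataError("need at least one trajectory")


def simulate_trajectories(config: TrajectoryConfig) -> TrajectorySet:
    """Log-normal fan around geometric growth on the 2025-2080 grid.

    Median across trajectories at each grid year is base·growth^j (the log
    noise has zero median); all counts are strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    years = np.array(GRID_YEARS)
    j = np.arange(len(years))
    median = config.base * config.growth**j

    sd_shared = config.dispersion * math.sqrt(config.shared_frac)
    sd_indep = config.dispersion * math.sqrt(1.0 - config.shared_frac)
    shared = rng.normal(0.0, 1.0, size=(config.n_trajectories, 1)) * sd_shared
    indep = rng.normal(0.0, 1.0, size=(config.n_trajectories, len(years))) * sd_indep
    counts = median[None, :] * np.exp(shared + indep)

    trajectories = [
        Trajectory(
            counts={int(y): float(c) for y, c in zip(years, counts[k])},
            trajectory_id=f"traj{k:04d}",
        )
        for k in range(config.n_trajectories)
    ]
    return TrajectorySet(trajectories=trajectories, source="synthetic")


def _fixture_text(name: str) -> str:
    return (
        importlib.resources.files("mradcast.data").joinpath(name).read_text(encoding="utf-8")
    )


def fixture_small() -> tuple[Dataset, TrajectorySet]:
    """The shipped deterministic fixture: 8 records over 2 countries (3 C1,
    5 C2; one bounded and one unbounded window; one year-only death, one
    unknown sex) plus 3 trajectories.  Byte-stable: built by reading the
    CSVs shipped with the package."""
    dataset = read_records(
        io.StringIO(_fixture_text("fixture_records.csv")),
        io.StringIO(_fixture_text("fixture_windows.csv")),
    )
    trajectories = read_trajectories(
        io.StringIO(_fixture_text("fixture_trajectories.csv")), label="fixture"
    )
    return dataset, trajectories
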