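"""Population-projection trajectories for the 110-114 age band.

Probabilistic projection software exposes uncertainty as a set of equally
weighted trajectories: each is one sampled future path of the count P of
people aged 110-114 at 5-year intervals.  A point-in-time count of the
110-114 band badly understates how many people *attained* age 110 in the
preceding 5 years, because most supercentenarians die within a year or two
of turning 110.  Under the exponential model with rate λ, if attainments
are uniform over (t-5, t], the expected band occupancy at t is
N (1 - e^{-5λ})/(5λ), so the attainment cohort is recovered as

    N = M(λ) · P,   M(λ) = 5λ / (1 - e^{-5λ})  (> 1, -> 1 as λ -> 0).

The grid years 2025, 2030, ..., 2080 therefore cover attainment cohorts
from 2020 through 2080, leaving those attaining 110 in 2080 time to die
before 2100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .records import DataError

__all__ = [
    "GRID_YEARS",
    "Trajectory",
    "TrajectorySet",
    "cohort_multiplier",
    "attainments",
    "total_attainments",
    "read_trajectories",
    "write_trajectories",
]

#: Default period-end grid: counts at year t describe attainments in (t-5, t].
GRID_YEARS = tuple(range(2025, 2085, 5))


@dataclass(frozen=True)
class Trajectory:
    """One projection path: period-end year -> count of people aged 110-114."""

    counts: Mapping[int, float]
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        years = sorted(self.counts)
        if not years:
            raise DataError(f"trajectory {self.trajectory_id!r} is empty")
        steps = np.diff(years)
        if len(steps) and not np.all(steps == 5):
            raise DataError(
                f"trajectory {self.trajectory_id!r}: years {years} are not a "
                "contiguous 5-year grid"
            )
        if any(v < 0 for v in self.counts.values()):
            raise DataError(f"trajectory {self.trajectory_id!r} has negative counts")
        object.__setattr__(self, "counts", dict(sorted(self.counts.items())))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.counts)

    @property
    def values(self) -> np.ndarray:
        return np.fromiter(self.counts.values(), dtype=float)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class TrajectorySet:
    """Equally weighted trajectories sharing one year grid."""

    trajectories: Sequence[Trajectory]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise DataError("trajectory set must contain at least one trajectory")
        grid = self.trajectories[0].years
        for traj in self.trajectories:
            if traj.years != grid:
                raise DataError(
                    f"trajectory {traj.trajectory_id!r} grid {traj.years} does not "
                    f"match the set grid {grid}"
                )
        object.__setattr__(self, "trajectories", tuple(self.trajectories))

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def years(self) -> tuple[int, ...]:
        return self.trajectories[0].years

    @property
    def totals(self) -> np.ndarray:
        """Summed band counts ΣP per trajectory (precomputed for forecasting)."""
        return np.array([t.total for t in self.trajectories])


def cohort_multiplier(lam):
    """M(λ) = 5λ / (1 - e^{-5λ}), the factor converting a 110-114 band count
    into the number who attained 110 during the preceding 5 years."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rate must be positive")
    out = 5.0 * lam / (-np.expm1(-5.0 * lam))
    return float(out) if out.ndim == 0 else out


def attainments(trajectory: Trajectory, lam: float) -> dict[int, float]:
    """Per-period attainment cohorts N_j = M(λ)·P_j, keyed by period-end year."""
    m = cohort_multiplier(lam)
    return {year: m * count for year, count in trajectory.counts.items()}


def total_attainments(trajectory: Trajectory, lam: float) -> float:
    """Total number attaining age 110 over the whole grid, M(λ)·ΣP."""
    return cohort_multiplier(lam) * trajectory.total


def read_trajectories(source: str | TextIO, label: str = "") -> TrajectorySet:
    """Read the long-format trajectory CSV: ``trajectory_id,year,count``."""
    frame = pd.read_csv(source, dtype={"trajectory_id": str})
    missing = [c for c in ("trajectory_id", "year", "count") if c not in frame.columns]
    if missing:
        raise DataError(f"trajectory input is missing columns {missing}")
    trajectories = []
    for tid, group in frame.groupby("trajectory_id", sort=True):
        counts = {int(y): float(c) for y, c in zip(group["year"], group["count"])}
        if len(counts) != len(group):
            raise DataError(f"trajectory {tid!r} has duplicate years")
        trajectories.append(Trajectory(counts=counts, trajectory_id=str(tid)))
    return TrajectorySet(trajectories=trajectories, source=label)


def write_trajectories(trajectory_set: TrajectorySet, stream: TextIO) -> None:
    rows = [
        (traj.trajectory_id, year, repr(count))
        for traj in trajectory_set.trajectories
        for year, count in traj.counts.items()
    ]
    pd.DataFrame(rows, columns=["trajectory_id", "year", "count"]).to_csv(stream, index=False)
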