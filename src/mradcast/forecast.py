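"""Monte Carlo composition of the unconditional MRAD distribution.

The maximum reported age at death (MRAD) over 2020-2100 depends on two
unknowns estimated from disjoint data: the plateau rate λ (posterior from
the truncated registry likelihood) and the future supercentenarian
population (empirical trajectory set from probabilistic projections).
Each Monte Carlo iteration draws one λ from the posterior and one
trajectory, converts the trajectory into a total age-110 attainment cohort
N = M(λ)·ΣP, and draws the maximum of N exponential excess lifetimes by
inverting its CDF (1 - e^{-λx})^N.  The 110 + x values across iterations
approximate the unconditional MRAD distribution, from which exceedance
tables and kernel-density summaries are read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .posterior import PosteriorSample
from .projections import TrajectorySet, cohort_multiplier
from .survival import sample_max

__all__ = ["MRADSamples", "forecast", "exceedance_table", "density_summary"]

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 100_000
DEFAULT_AGE_GRID = tuple(range(120, 144, 2))


@dataclass(frozen=True)
class MRADSamples:
    """Monte Carlo draws of the maximum age at death 2020-2100.

    ``ages`` holds the retained draws (all >= 110); iterations whose drawn
    trajectory implied an empty attainment cohort are tallied in
    ``n_degenerate`` and excluded, so probabilities computed against ``T``
    remain unconditional.
    """

    ages: np.ndarray
    T: int
    seed: int
    n_degenerate: int = 0
    provenance: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if len(self.ages) + self.n_degenerate != self.T:
            raise ValueError("retained draws + degenerate tally must equal T")
        if len(self.ages) and np.min(self.ages) < 110.0:
            raise ValueError("all MRAD draws must be at least 110")


def forecast(
    posterior: PosteriorSample,
    trajectories: TrajectorySet,
    T: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> MRADSamples:
    """Compose posterior and projection uncertainty into MRAD draws.

    Per iteration: λ ~ uniform over posterior draws, trajectory ~ uniform
    over the set (independently, reflecting the disjoint data sources),
    N = M(λ)·ΣP, then one inverse-CDF draw of the maximum of N lifetimes.
    Iterations with N = 0 record the degenerate no-supercentenarian
    outcome; if every iteration is degenerate this is an error.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    if len(posterior.draws) == 0:
        raise ValueError("posterior sample is empty")
    rng = np.random.default_rng(seed)

    lam = rng.choice(posterior.draws, size=T, replace=True)
    traj_idx = rng.integers(0, len(trajectories), size=T)
    band_totals = trajectories.totals[traj_idx]
    n_attain = cohort_multiplier(lam) * band_totals

    live = n_attain > 0
    n_degenerate = int(T - live.sum())
    if n_degenerate == T:
        raise ValueError(
            f"all {T} iterations had an empty attainment cohort (all-zero trajectories)"
        )
    if n_degenerate:
        logger.info("forecast: %d of %d iterations degenerate (N = 0)", n_degenerate, T)
    u = rng.uniform(size=T)
    ages = 110.0 + sample_max(lam[live], n_attain[live], u[live])
    return MRADSamples(
        ages=ages,
        T=T,
        seed=seed,
        n_degenerate=n_degenerate,
        provenance=(f"posterior(seed={posterior.seed})", trajectories.source),
    )


def exceedance_table(
    samples: MRADSamples, ages: Sequence[int] = DEFAULT_AGE_GRID
) -> dict[int, float]:
    """P(MRAD >= a) for each age a on the grid — the probability someone
    attains age a at last birthday during the period.

    Degenerate iterations count in the denominator (below every age), so
    the probabilities are unconditional.
    """
    if samples.T == 0 or len(samples.ages) == 0:
        raise ValueError("cannot tabulate an empty sample")
    draws = np.sort(samples.ages)
    out: dict[int, float] = {}
    for age in ages:
        n_ge = len(draws) - int(np.searchsorted(draws, float(age), side="left"))
        out[int(age)] = n_ge / samples.T
    return out


def density_summary(
    samples: MRADSamples, bandwidth: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of the MRAD draws on a 0.1-year age grid.

    Silverman's rule by default; ``bandwidth`` (in years) overrides it.
    Returns (grid, density); the grid spans the draws plus a 3-bandwidth
    margin so the density integrates to 1 on it.
    """
    draws = samples.ages
    if len(draws) < 100:
        raise ValueError("density summary requires at least 100 draws")
    if bandwidth is None:
        kde = stats.gaussian_kde(draws, bw_method="silverman")
    else:
        kde = stats.gaussian_kde(draws, bw_method=bandwidth / float(np.std(draws, ddof=1)))
    h = kde.factor * float(np.std(draws, ddof=1))
    lo = np.floor((draws.min() - 3.0 * h) * 10.0) / 10.0
    hi = np.ceil((draws.max() + 3.0 * h) * 10.0) / 10.0
    grid = np.arange(lo, hi + 0.05, 0.1)
    return grid, kde(grid)
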