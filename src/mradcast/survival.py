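"""Truncation-aware survival models for excess lifetimes beyond age 110.

The working model is that excess age at death X = (age at death) - 110 is
Exponential(λ): the mortality-plateau hypothesis, under which the one-year
survival probability e^{-λ} is the same at every age past 110.  The
alternative used for model checking is the Generalized Pareto (GP) family
with location fixed at 0, which nests the exponential at shape ξ = 0.

Because a record is observable only if the death falls inside its country
window, each record's likelihood contribution is its density divided by the
probability that a death with the same age-110 attainment time would have
been observable at all:

    C1 (t <= b):  f(x) / [F(e - t) - F(b - t)]
    C2 (t > b):   f(x) / F(e - t)

with F the family's CDF on excess age.  Both cases reduce to
f(x) / [F(hi) - F(lo)] with lo = max(b - t, 0) and hi = e - t, which is how
the module computes them.

Also provided: maximum-likelihood fitting (optionally stratified by sex
and/or region) with parametric-bootstrap percentile intervals, likelihood
ratio / BIC model comparison, and the distribution of the maximum of N
exponential lifetimes used by the forecasting stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .records import Dataset, DataError, DeathRecord, ObservationWindow
from .regions import region_of

__all__ = [
    "ExpParams",
    "GPParams",
    "FitResult",
    "TestResult",
    "log_contribution",
    "loglik",
    "fit_mle",
    "bootstrap_ci",
    "lrt",
    "delta_bic",
    "one_year_survival",
    "mean_lifetime_ci",
    "max_order_pdf",
    "max_order_cdf",
    "sample_max",
]

_LAMBDA_BOUNDS = (1e-6, 50.0)


@dataclass(frozen=True)
class ExpParams:
    """Exponential excess-lifetime model: rate λ per year, mean 1/λ."""

    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n_params(self) -> int:
        return 1


@dataclass(frozen=True)
class GPParams:
    """Generalized Pareto excess-lifetime model with location fixed at 0.

    ``shape`` ξ = 0 recovers the exponential with rate 1/scale; ξ < 0 gives
    a bounded support [0, -scale/shape].
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def n_params(self) -> int:
        return 2


Params = ExpParams | GPParams


def _distribution(params: Params):
    if isinstance(params, ExpParams):
        return stats.expon(scale=1.0 / params.rate)
    return stats.genpareto(c=params.shape, loc=0.0, scale=params.scale)


def _log_window_prob(params: Params, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """log P(lo <= X <= hi) for the observable excess-age set.

    Uses survival functions so an unbounded window end (hi = inf) is exact,
    and a log1p/expm1 path for the exponential to keep near-full windows
    accurate.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if isinstance(params, ExpParams):
        lam = params.rate
        # P = e^{-λ lo} - e^{-λ hi} = e^{-λ lo} (1 - e^{-λ (hi - lo)})
        tail = np.exp(-lam * (hi - lo))  # exp(-inf) = 0 for unbounded windows
        log_p = -lam * lo + np.log1p(-tail)
    else:
        dist = _distribution(params)
        p = dist.sf(lo) - np.where(np.isinf(hi), 0.0, dist.sf(hi))
        with np.errstate(divide="ignore"):
            log_p = np.log(p)
    if np.any(~np.isfinite(log_p)):
        raise DataError(
            "observable-window probability is zero for at least one record: "
            "the parameter/window configuration is observationally impossible"
        )
    return log_p


def _log_density(params: Params, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if isinstance(params, ExpParams):
        # direct form; avoids per-call construction of a frozen distribution
        return math.log(params.rate) - params.rate * x
    dist = _distribution(params)
    with np.errstate(divide="ignore"):
        return dist.logpdf(x)


def log_contribution(
    record: DeathRecord, window: ObservationWindow, params: Params
) -> float:
    """Log-likelihood contribution of a single record under its window.

    Returns -inf (not an error) when x lies outside a bounded GP support;
    raises if the window itself has zero observable probability.
    """
    lo = max(window.start - record.attainment_time, 0.0)
    hi = window.end - record.attainment_time
    log_f = float(_log_density(params, np.array([record.excess_age]))[0])
    log_p = float(_log_window_prob(params, np.array([lo]), np.array([hi]))[0])
    return log_f - log_p


def loglik(dataset: Dataset, params: Params) -> float:
    """Truncation-aware log-likelihood: sum of per-record contributions."""
    if dataset.n == 0:
        return 0.0
    log_f = _log_density(params, dataset.excess_ages)
    if np.any(np.isneginf(log_f)):
        return -math.inf
    log_p = _log_window_prob(params, dataset.lower_bounds, dataset.upper_bounds)
    return float(np.sum(log_f - log_p))


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit: family label, parameters (a single Params
    or a group -> Params map for stratified fits), maximized log-likelihood
    and sample size; confidence intervals attach after bootstrapping."""

    family: str
    params: Params | Mapping[str, Params]
    loglik: float
    n: int
    ci: Mapping[str, tuple[float, float]] | None = None
    ci_method: str | None = None

    @property
    def n_params(self) -> int:
        if isinstance(self.params, (ExpParams, GPParams)):
            return self.params.n_params
        return sum(p.n_params for p in self.params.values())


def _fit_exponential(dataset: Dataset) -> tuple[ExpParams, float]:
    x = dataset.excess_ages
    if dataset.n == 0:
        raise DataError("cannot fit a model to an empty dataset")
    if not np.sum(x) > 0:
        raise DataError("sum of excess ages is zero; exponential MLE undefined")
    res = optimize.minimize_scalar(
        lambda lam: -loglik(dataset, ExpParams(lam)),
        bounds=_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"exponential fit failed to converge: {res.message}")
    params = ExpParams(float(res.x))
    return params, -float(res.fun)


def _fit_gp(dataset: Dataset) -> tuple[GPParams, float]:
    exp_params, _ = _fit_exponential(dataset)

    def neg(theta: np.ndarray) -> float:
        sigma = math.exp(theta[0])
        ll = loglik(dataset, GPParams(scale=sigma, shape=theta[1]))
        return math.inf if not np.isfinite(ll) else -ll

    start = np.array([math.log(1.0 / exp_params.rate), 0.0])
    rough = optimize.minimize(neg, start, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8})
    polish = optimize.minimize(neg, rough.x, method="BFGS")
    best = polish if polish.fun <= rough.fun else rough
    if not np.isfinite(best.fun):
        raise RuntimeError("GP fit failed: no finite-likelihood optimum found")
    params = GPParams(scale=math.exp(best.x[0]), shape=float(best.x[1]))
    return params, -float(best.fun)


def _group_key(record: DeathRecord, grouping: str) -> str:
    if grouping == "sex":
        return record.sex
    if grouping == "region":
        return region_of(record.country)
    if grouping == "sex-within-region":
        return f"{region_of(record.country)}/{record.sex}"
    raise ValueError(f"unknown grouping {grouping!r}")


def fit_mle(
    dataset: Dataset, family: str = "exponential", grouping: str = "none"
) -> FitResult:
    """Maximize the truncated likelihood.

    ``family`` is ``exponential`` (bounded 1-D search for λ) or ``gp``
    (2-D search in (log σ, ξ) started at the exponential solution).
    ``grouping`` stratifies by ``sex``, ``region`` or ``sex-within-region``;
    groups are fitted independently and the log-likelihoods summed.
    """
    if family not in ("exponential", "gp"):
        raise ValueError(f"unknown family {family!r}")
    fit_one = _fit_exponential if family == "exponential" else _fit_gp
    if grouping == "none":
        params, ll = fit_one(dataset)
        return FitResult(family=family, params=params, loglik=ll, n=dataset.n)

    keys = [_group_key(r, grouping) for r in dataset.records]
    fitted: dict[str, Params] = {}
    total = 0.0
    for key in sorted(set(keys)):
        sub = dataset.subset([k == key for k in keys])
        if sub.n == 0:
            raise DataError(f"group {key!r} has no records")
        params, ll = fit_one(sub)
        fitted[key] = params
        total += ll
    return FitResult(family=family, params=fitted, loglik=total, n=dataset.n)


def _sample_truncated(
    params: Params, lo: np.ndarray, hi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw x | lo <= X <= hi per record via the inverse CDF."""
    dist = _distribution(params)
    cdf_lo = dist.cdf(lo)
    cdf_hi = np.where(np.isinf(hi), 1.0, dist.cdf(hi))
    u = rng.uniform(cdf_lo, cdf_hi)
    return dist.ppf(u)


def _rebuild_with_excess(dataset: Dataset, x_new: np.ndarray) -> Dataset:
    recs = [
        replace(
            r,
            excess_age=float(x),
            death_time=r.attainment_time + float(x),
            birth_date_source="",
            death_date_source="",
            death_year_only_source="",
        )
        for r, x in zip(dataset.records, x_new)
    ]
    return Dataset(recs, dataset.windows)


def bootstrap_ci(
    dataset: Dataset,
    fit: FitResult,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> FitResult:
    """Parametric-bootstrap percentile intervals for an ungrouped fit.

    Each replicate holds every record's attainment time and window fixed and
    redraws its excess age from the fitted law conditioned on observability
    (the same conditioning the likelihood uses), then refits.  Replicates
    whose refit fails are dropped; more than 5% failures is an error.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not isinstance(fit.params, (ExpParams, GPParams)):
        raise NotImplementedError("bootstrap_ci supports ungrouped fits")
    rng = np.random.default_rng(seed)
    fit_one = _fit_exponential if fit.family == "exponential" else _fit_gp
    lo, hi = dataset.lower_bounds, dataset.upper_bounds

    estimates: list[tuple[float, ...]] = []
    failures = 0
    for _ in range(B):
        x_new = _sample_truncated(fit.params, lo, hi, rng)
        try:
            boot_params, _ = fit_one(_rebuild_with_excess(dataset, x_new))
        except (DataError, RuntimeError):
            failures += 1
            continue
        if isinstance(boot_params, ExpParams):
            estimates.append((boot_params.rate,))
        else:
            estimates.append((boot_params.scale, boot_params.shape))
    if failures > 0.05 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")

    arr = np.asarray(estimates)
    alpha = (1.0 - level) / 2.0
    los = np.quantile(arr, alpha, axis=0)
    his = np.quantile(arr, 1.0 - alpha, axis=0)
    names = ("rate",) if fit.family == "exponential" else ("scale", "shape")
    ci = {name: (float(l), float(h)) for name, l, h in zip(names, los, his)}
    return replace(fit, ci=ci, ci_method=f"parametric bootstrap percentile (B={B - failures})")


@dataclass(frozen=True)
class TestResult:
    """Likelihood-ratio / BIC comparison of nested truncated fits.

    ``delta_bic`` follows the convention df·ln(n) - Λ: positive values
    favour the simpler null model.
    """

    df: int
    statistic: float
    p_value: float
    delta_bic: float
    n_used: int


def delta_bic(df: int, statistic: float, n_used: int) -> float:
    """BIC difference (null minus alternative) from the LRT statistic:
    df·ln(n) - Λ, positive favouring the null."""
    return df * math.log(n_used) - statistic


def lrt(null_fit: FitResult, alt_fit: FitResult) -> TestResult:
    """Likelihood ratio test of a nested null against an alternative fit
    on the same records, with the chi-square(df) reference."""
    df = alt_fit.n_params - null_fit.n_params
    if df < 1:
        raise ValueError("alternative must have more parameters than the null")
    if null_fit.n != alt_fit.n:
        raise ValueError("null and alternative were fitted to different record counts")
    if alt_fit.loglik < null_fit.loglik - 1e-6:
        raise RuntimeError(
            "alternative log-likelihood below null beyond tolerance: optimizer failure"
        )
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    p = float(stats.chi2.sf(stat, df))
    return TestResult(
        df=df,
        statistic=stat,
        p_value=p,
        delta_bic=delta_bic(df, stat, null_fit.n),
        n_used=null_fit.n,
    )


def one_year_survival(params: ExpParams) -> float:
    """P(survive one more year | current age), constant at e^{-λ} under the
    memoryless exponential model."""
    return math.exp(-params.rate)


def mean_lifetime_ci(
    rate: float, rate_ci: tuple[float, float]
) -> tuple[float, tuple[float, float]]:
    """Convert a rate estimate and CI into the mean excess lifetime 1/λ and
    its CI (endpoints swap under the reciprocal)."""
    lo, hi = rate_ci
    if not (0 < lo <= rate <= hi):
        raise ValueError("rate CI must be positive and contain the point estimate")
    return 1.0 / rate, (1.0 / hi, 1.0 / lo)


def _check_max_order_args(lam: float, n: float) -> None:
    if not lam > 0:
        raise ValueError(f"rate must be positive, got {lam}")
    if not n > 0:
        raise ValueError(f"N must be positive, got {n}")


def max_order_pdf(x, lam: float, n: float):
    """Density of the maximum of N iid Exponential(λ) lifetimes,
    N λ e^{-λx} (1 - e^{-λx})^{N-1}.  N may be non-integer (continuous
    extension, as produced by the cohort multiplier)."""
    _check_max_order_args(lam, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    out = n * lam * np.exp(-lam * x) * (-np.expm1(-lam * x)) ** (n - 1.0)
    return float(out) if out.ndim == 0 else out


def max_order_cdf(x, lam: float, n: float):
    """CDF of the maximum: (1 - e^{-λx})^N, computed as exp(N·log1p(-e^{-λx}))."""
    _check_max_order_args(lam, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    with np.errstate(divide="ignore"):
        out = np.exp(n * np.log1p(-np.exp(-lam * x)))
    return float(out) if out.ndim == 0 else out


def sample_max(lam, n, u):
    """Invert the maximum-order-statistic CDF: x = -ln(1 - u^{1/N})/λ.

    Vectorized over any mix of scalar/array arguments; ``u`` must lie
    strictly in (0, 1).  Computed as -ln(-expm1(ln(u)/N))/λ for accuracy at
    large N.
    """
    lam = np.asarray(lam, dtype=float)
    n = np.asarray(n, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(lam <= 0) or np.any(n <= 0):
        raise ValueError("rate and N must be positive")
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    out = -np.log(-np.expm1(np.log(u) / n)) / lam
    return float(out) if out.ndim == 0 else out
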