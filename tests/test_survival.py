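import math

import numpy as np
import pytest
from scipy import integrate, stats

from mradcast.records import DataError, DeathRecord, ObservationWindow
from mradcast.survival import (
    ExpParams,
    GPParams,
    bootstrap_ci,
    delta_bic,
    fit_mle,
    log_contribution,
    loglik,
    lrt,
    max_order_cdf,
    max_order_pdf,
    mean_lifetime_ci,
    one_year_survival,
    sample_max,
)

from conftest import make_dataset, untruncated_exponential_dataset


def _record(t, x, country="US"):
    return DeathRecord("r", country, "F", t, t + x, x)


class TestLogContribution:
    def test_c2_unbounded_reduces_to_log_density(self):
        win = ObservationWindow("US", start=1999.0)  # t > b, e = inf
        val = log_contribution(_record(2000.0, 1.0), win, ExpParams(1.0))
        assert val == pytest.approx(math.log(1.0) - 1.0, abs=1e-12)

    def test_c1_with_zero_offset_and_unbounded_end(self):
        win = ObservationWindow("US", start=2000.0)  # t = b: C1, denominator 1
        val = log_contribution(_record(2000.0, 1.0), win, ExpParams(1.0))
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_c2_bounded_matches_formula_and_quadrature(self):
        lam, x, e_minus_t = 0.7, 0.8, 2.0
        win = ObservationWindow("US", start=1999.0, end=2000.0 + e_minus_t)
        val = log_contribution(_record(2000.0, x), win, ExpParams(lam))
        expected = math.log(lam * math.exp(-lam * x)) - math.log(1 - math.exp(-lam * e_minus_t))
        assert val == pytest.approx(expected, abs=1e-12)
        # independent route: normalizer by numeric integration of the density
        norm, _ = integrate.quad(lambda s: lam * math.exp(-lam * s), 0.0, e_minus_t)
        assert val == pytest.approx(math.log(lam * math.exp(-lam * x) / norm), abs=1e-9)

    def test_impossible_window_raises(self):
        # bounded GP support [0, 2] cannot produce a death inside a window
        # that opens 3 years after attainment: zero observable probability
        win = ObservationWindow("US", start=2003.0, end=2005.0)
        with pytest.raises(DataError, match="impossible"):
            log_contribution(
                _record(2000.0, 3.5), win, GPParams(scale=1.0, shape=-0.5)
            )

    def test_gp_out_of_support_is_minus_inf(self):
        win = ObservationWindow("US", start=1990.0)
        # shape -0.5, scale 1 -> support [0, 2]; x = 3 is impossible
        val = log_contribution(_record(2000.0, 3.0), win, GPParams(scale=1.0, shape=-0.5))
        assert val == -math.inf

    @pytest.mark.parametrize("family", ["exponential", "gp"])
    @pytest.mark.parametrize(
        "start,end", [(2002.0, 2006.0), (2002.0, math.inf), (1999.0, 2003.0), (1999.0, math.inf)]
    )
    def test_conditional_density_normalizes(self, family, start, end):
        # exp(log contribution) must integrate to 1 over the observable set,
        # for both families and both truncation cases
        params = ExpParams(0.733) if family == "exponential" else GPParams(0.9, 0.2)
        win = ObservationWindow("US", start=start, end=end)
        t = 2000.0
        lo = max(start - t, 0.0)
        hi = np.inf if math.isinf(end) else end - t
        total, err = integrate.quad(
            lambda s: math.exp(log_contribution(_record(t, s), win, params)),
            lo,
            hi,
            limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLoglik:
    def test_empty_dataset_is_zero(self):
        ds = make_dataset([])
        assert loglik(ds, ExpParams(0.7)) == 0.0

    def test_additivity(self):
        one = make_dataset([1.3])
        two = make_dataset([1.3, 1.3])
        assert loglik(two, ExpParams(0.9)) == pytest.approx(
            2 * loglik(one, ExpParams(0.9)), abs=1e-10
        )

    def test_grid_argmax_matches_fit(self, fixture_dataset):
        grid = np.linspace(0.1, 3.0, 50)
        values = [loglik(fixture_dataset, ExpParams(l)) for l in grid]
        best = grid[int(np.argmax(values))]
        fitted = fit_mle(fixture_dataset).params.rate
        assert abs(best - fitted) <= grid[1] - grid[0]

    def test_gp_at_tiny_shape_matches_exponential(self, fixture_dataset):
        lam = 0.8
        ll_exp = loglik(fixture_dataset, ExpParams(lam))
        ll_gp = loglik(fixture_dataset, GPParams(scale=1.0 / lam, shape=1e-6))
        assert ll_gp == pytest.approx(ll_exp, abs=1e-4)


class TestFitMLE:
    def test_closed_form_untruncated(self):
        ds = make_dataset([2.0])
        assert fit_mle(ds).params.rate == pytest.approx(0.5, abs=1e-8)

    def test_closed_form_untruncated_many(self):
        ds = untruncated_exponential_dataset(500, 0.733, seed=1)
        expected = ds.n / ds.excess_ages.sum()
        assert fit_mle(ds).params.rate == pytest.approx(expected, abs=1e-8)

    def test_gp_consistency(self):
        rng = np.random.default_rng(3)
        x = stats.genpareto(c=0.3, scale=1.0).rvs(5000, random_state=rng)
        ds = make_dataset(x)
        fit = fit_mle(ds, family="gp")
        assert fit.params.shape == pytest.approx(0.3, abs=0.05)

    def test_grouped_fit_sums_logliks(self, fixture_dataset):
        grouped = fit_mle(fixture_dataset, grouping="sex")
        total = 0.0
        for sex, params in grouped.params.items():
            sub = fixture_dataset.subset([r.sex == sex for r in fixture_dataset])
            total += loglik(sub, params)
        assert grouped.loglik == pytest.approx(total, abs=1e-9)
        assert grouped.loglik >= fit_mle(fixture_dataset).loglik - 1e-9

    def test_empty_dataset_raises(self):
        with pytest.raises(DataError):
            fit_mle(make_dataset([]))


class TestBootstrapCI:
    def test_same_seed_reproduces_interval(self, fixture_dataset):
        fit = fit_mle(fixture_dataset)
        a = bootstrap_ci(fixture_dataset, fit, B=100, seed=5)
        b = bootstrap_ci(fixture_dataset, fit, B=100, seed=5)
        assert a.ci == b.ci

    def test_interval_contains_point_estimate(self, fixture_dataset):
        fit = fit_mle(fixture_dataset)
        with_ci = bootstrap_ci(fixture_dataset, fit, B=200, seed=5)
        lo, hi = with_ci.ci["rate"]
        assert lo <= fit.params.rate <= hi

    def test_untruncated_percentile_close_to_wald(self):
        # asymptotic oracle: percentile CI ~ rate_hat (1 +/- 1.96/sqrt(n))
        ds = untruncated_exponential_dataset(1119, 0.733, seed=9)
        fit = fit_mle(ds)
        with_ci = bootstrap_ci(ds, fit, B=400, seed=17)
        lo, hi = with_ci.ci["rate"]
        rate = fit.params.rate
        wald_lo = rate * (1 - 1.96 / math.sqrt(ds.n))
        wald_hi = rate * (1 + 1.96 / math.sqrt(ds.n))
        assert lo == pytest.approx(wald_lo, rel=0.10)
        assert hi == pytest.approx(wald_hi, rel=0.10)


class TestModelComparison:
    @pytest.mark.parametrize(
        "df,stat,n,expected",
        [(1, 0.39, 1119, 6.63), (3, 6.74, 1119, 14.32), (1, 0.42, 1119, 6.60)],
    )
    def test_bic_from_lrt_statistic(self, df, stat, n, expected):
        assert delta_bic(df, stat, n) == pytest.approx(expected, abs=5e-3)

    def test_bic_at_zero_statistic(self):
        assert delta_bic(1, 0.0, 3) == pytest.approx(math.log(3))

    def test_lrt_on_nested_fits(self, fixture_dataset):
        null = fit_mle(fixture_dataset)
        alt = fit_mle(fixture_dataset, family="gp")
        res = lrt(null, alt)
        assert res.df == 1
        assert res.statistic >= 0
        assert 0 <= res.p_value <= 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))
        assert res.delta_bic == pytest.approx(math.log(fixture_dataset.n) - res.statistic)

    def test_lrt_rejects_optimizer_failure(self, fixture_dataset):
        null = fit_mle(fixture_dataset)
        bad_alt = fit_mle(fixture_dataset, family="gp")
        worse = type(bad_alt)(
            family="gp", params=bad_alt.params, loglik=null.loglik - 1.0, n=bad_alt.n
        )
        with pytest.raises(RuntimeError, match="optimizer"):
            lrt(null, worse)


class TestRateSummaries:
    def test_one_year_survival(self):
        assert one_year_survival(ExpParams(math.log(2))) == pytest.approx(0.5)
        assert one_year_survival(ExpParams(1e-9)) == pytest.approx(1.0)
        assert one_year_survival(ExpParams(0.733)) == pytest.approx(0.4805, abs=5e-5)

    def test_mean_lifetime_ci_swaps_endpoints(self):
        mean, (lo, hi) = mean_lifetime_ci(0.733, (0.689, 0.781))
        assert mean == pytest.approx(1.364, abs=5e-4)
        assert lo == pytest.approx(1.280, abs=5e-4)
        assert hi == pytest.approx(1.451, abs=5e-4)


class TestMaxOrderStatistic:
    def test_n_one_reduces_to_exponential_density(self):
        x = np.linspace(0.0, 10.0, 25)
        assert np.allclose(max_order_pdf(x, 0.9, 1.0), 0.9 * np.exp(-0.9 * x))

    def test_density_integrates_to_one(self):
        lam, n = 1.0 / 1.34, 2974.0
        total, _ = integrate.quad(lambda s: max_order_pdf(s, lam, n), 0.0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pdf_is_derivative_of_cdf(self):
        lam, n, x = 0.7, 1000.0, 10.0
        h = 1e-5
        numeric = (max_order_cdf(x + h, lam, n) - max_order_cdf(x - h, lam, n)) / (2 * h)
        assert max_order_pdf(x, lam, n) == pytest.approx(numeric, abs=1e-6)

    def test_cdf_limits_and_value(self):
        assert max_order_cdf(0.0, 0.7, 1000.0) == 0.0
        assert max_order_cdf(1e4, 0.7, 1000.0) == pytest.approx(1.0)
        assert 1.0 - max_order_cdf(10.0, 0.7, 1000.0) == pytest.approx(0.598, abs=5e-4)

    def test_cdf_monotone_in_x_and_n(self):
        xs = np.linspace(0.01, 20.0, 80)
        cdf = max_order_cdf(xs, 0.733, 500.0)
        assert np.all(np.diff(cdf) >= 0)
        for x in (0.5, 2.0, 8.0):
            values = [max_order_cdf(x, 0.733, n) for n in (1.0, 10.0, 500.0, 2974.0)]
            assert all(a >= b for a, b in zip(values, values[1:]))

    def test_sampler_inverts_cdf(self):
        lam, n = 0.733, 500.0
        for x in (0.5, 2.0, 5.0, 9.0):
            u = max_order_cdf(x, lam, n)
            assert sample_max(lam, n, u) == pytest.approx(x, abs=1e-10)

    def test_sampler_passes_ks_against_analytic_cdf(self):
        lam, n = 0.733, 500.0
        rng = np.random.default_rng(21)
        draws = sample_max(lam, n, rng.uniform(size=10_000))
        res = stats.kstest(draws, lambda s: max_order_cdf(s, lam, n))
        assert res.pvalue > 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            max_order_pdf(-1.0, 0.7, 10.0)
        with pytest.raises(ValueError):
            sample_max(0.7, 10.0, 1.0)
        with pytest.raises(ValueError):
            sample_max(0.7, 10.0, 0.0)
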