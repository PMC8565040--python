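import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from alcmeta.gammadist import (
    CategoryThresholds,
    GammaConsumption,
    category_shares,
    category_volume_shares,
    from_moments,
    interval_log_probability,
    interval_probability,
    quantile,
)


class TestFromMoments:
    def test_male_shape_ratio(self):
        # sd/mu ratio 1.171 implies the male shape constant
        g = from_moments(50.0, 50.0 * 1.171)
        assert g.alpha == pytest.approx(1.171**-2, rel=1e-12)
        assert g.beta == pytest.approx(g.alpha / 50.0, rel=1e-12)

    def test_unit_moments_give_exponential(self):
        g = from_moments(1.0, 1.0)
        assert (g.alpha, g.beta) == (1.0, 1.0)

    def test_round_trip_machine_precision(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            alpha = rng.uniform(0.1, 5.0)
            beta = rng.uniform(0.01, 2.0)
            g0 = GammaConsumption(alpha, beta)
            g1 = from_moments(float(g0.mu), float(g0.sd))
            assert g1.alpha == pytest.approx(alpha, rel=1e-12)
            assert g1.beta == pytest.approx(beta, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            from_moments(0.0, 1.0)
        with pytest.raises(ValueError):
            from_moments(1.0, -1.0)


class TestIntervalProbability:
    def test_total_mass(self):
        g = GammaConsumption(0.73, 0.0146)
        assert interval_probability(0, math.inf, g) == pytest.approx(1.0)

    def test_exponential_median(self):
        assert interval_probability(0, math.log(2), (1.0, 1.0)) == pytest.approx(0.5)

    def test_coverage_scaling_property(self):
        # halving coverage halves the reported scale: P([10,20]; c=1/2)
        # equals P([20,40]; c=1)
        g = GammaConsumption(0.73, 0.73 / 50)
        p_half = interval_probability(10, 20, g, coverage=0.5)
        p_full = interval_probability(20, 40, g, coverage=1.0)
        assert p_half == pytest.approx(p_full, abs=1e-12)

    def test_scaling_property_randomised(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            alpha = rng.uniform(0.2, 3.0)
            beta = rng.uniform(0.005, 1.0)
            c = rng.uniform(0.1, 1.0)
            lo = rng.uniform(0, 50)
            hi = lo + rng.uniform(0.1, 50)
            p1 = interval_probability(lo, hi, (alpha, beta), c)
            p2 = interval_probability(lo / c, hi / c, (alpha, beta), 1.0)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_degenerate_interval_returns_density(self):
        g = GammaConsumption(0.8, 0.05)
        x = 17.0
        c = 0.6
        expected = stats.gamma.pdf(x, a=0.8, scale=c / 0.05)
        assert interval_probability(x, x, g, c) == pytest.approx(expected, rel=1e-12)
        assert interval_log_probability(x, x, g, c) == pytest.approx(
            math.log(expected), rel=1e-12)

    def test_partition_additivity(self):
        g = GammaConsumption(0.63, 0.02)
        edges = [0.0, 1.0, 5.0, 12.0, 40.0, 90.0, math.inf]
        total = sum(interval_probability(a, b, g)
                    for a, b in zip(edges[:-1], edges[1:]))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            alpha = rng.uniform(0.3, 2.5)
            beta = rng.uniform(0.01, 0.5)
            c = rng.uniform(0.2, 1.0)
            lo = rng.uniform(0, 30)
            hi = lo + rng.uniform(0.5, 60)
            ref, _ = integrate.quad(
                lambda x: stats.gamma.pdf(x, a=alpha, scale=c / beta), lo, hi)
            assert interval_probability(lo, hi, (alpha, beta), c) == pytest.approx(
                ref, abs=1e-8)

    def test_negative_lower_bound_rejected(self):
        with pytest.raises(ValueError):
            interval_probability(-1.0, 2.0, (1.0, 1.0))


class TestQuantile:
    def test_exponential_median(self):
        assert quantile(0.5, (1.0, 1.0)) == pytest.approx(math.log(2))

    def test_inverse_identity(self):
        g = GammaConsumption(0.73, 0.0146)
        for x in (1.0, 10.0, 55.0, 200.0):
            p = interval_probability(0, x, g)
            assert quantile(p, g) == pytest.approx(x, rel=1e-9)

    def test_matches_bisection(self):
        g = GammaConsumption(0.73, 0.73 / 50)
        q95 = quantile(0.95, g)
        ref = optimize.brentq(
            lambda x: stats.gamma.cdf(x, a=0.73, scale=50 / 0.73) - 0.95,
            1e-6, 1e4, xtol=1e-10)
        assert q95 == pytest.approx(ref, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            quantile(0.0, (1.0, 1.0))
        with pytest.raises(ValueError):
            quantile(1.0, (1.0, 1.0))


class TestCategories:
    thr = CategoryThresholds(24.0, 60.0)

    def test_tiny_mean_is_all_light(self):
        g = from_moments(0.01, 0.01)
        p_light, _, _ = category_shares(g, self.thr)
        assert p_light == pytest.approx(1.0, abs=1e-9)

    def test_exponential_closed_form(self):
        g = from_moments(24.0, 24.0)  # exponential with mean 24
        p_light, p_int, p_heavy = category_shares(g, CategoryThresholds(24, 60))
        assert p_light == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert p_heavy == pytest.approx(math.exp(-60 / 24), rel=1e-12)
        assert p_light + p_int + p_heavy == pytest.approx(1.0, abs=1e-12)

    def test_exponential_partial_moment(self):
        # int_0^t x e^-x dx = 1 - (1+t) e^-t for the unit exponential
        g = from_moments(1.0, 1.0)
        t = 1.7
        (v_light, _, _), _ = category_volume_shares(
            g, CategoryThresholds(t, 10.0))
        assert v_light == pytest.approx(1 - (1 + t) * math.exp(-t), rel=1e-12)

    def test_volume_shares_match_quadrature(self):
        g = GammaConsumption(0.73, 0.73 / 50)
        vols, means = category_volume_shares(g, self.thr)
        mu = 50.0
        f = lambda x: x * stats.gamma.pdf(x, a=0.73, scale=50 / 0.73)
        ref_light = integrate.quad(f, 0, 24)[0] / mu
        ref_heavy = integrate.quad(f, 60, np.inf)[0] / mu
        assert vols[0] == pytest.approx(ref_light, abs=1e-8)
        assert vols[2] == pytest.approx(ref_heavy, abs=1e-8)
        assert sum(float(v) for v in vols) == pytest.approx(1.0, abs=1e-12)

    def test_volume_conservation(self):
        g = GammaConsumption(0.65, 0.65 / 45)
        vols, means = category_volume_shares(g, self.thr)
        probs = category_shares(g, self.thr)
        mu = 45.0
        total = sum(float(p) * float(m) for p, m in zip(probs, means))
        assert total == pytest.approx(mu, rel=1e-10)

    def test_empty_category_mean_is_nan(self):
        g = from_moments(0.01, 0.01)  # essentially no heavy drinkers
        _, means = category_volume_shares(g, CategoryThresholds(200.0, 400.0))
        assert np.isnan(float(means[2]))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            CategoryThresholds(60.0, 24.0)
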